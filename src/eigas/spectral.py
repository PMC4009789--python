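"""Smooth contact matrices and per-residue eigenvalue fingerprints.

The structural signature of a chain is built in two steps.  First the Cα
trace is turned into a smooth contact matrix

    C_kt = 1 − d_kt/κ   if d_kt ≤ κ,   else 0,

where d_kt is the Euclidean distance (Å) between residues k and t and κ is
the contact cutoff.  C has unit diagonal, so trace(C) = n.  Second, C is
eigendecomposed, C = U D Uᵀ, and each residue i is assigned the eigenvalue
of the nearest eigenspace: with R = √D Uᵀ (the columns of R are the
intrinsic contact vectors), residue i receives λ_p where |R_pi| is maximal
over rows p with λ_p > 0.  Aligning two proteins then reduces to comparing
two sequences of eigenvalues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import IO

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .structures import CalphaChain

logger = logging.getLogger(__name__)

__all__ = [
    "ContactMatrix",
    "SpectralFingerprint",
    "contact_matrix",
    "spectral_fingerprint",
    "fingerprint_chain",
    "write_fingerprint",
]


@dataclass
class ContactMatrix:
    """Smooth contact matrix of a chain at cutoff ``cutoff`` (Å)."""

    matrix: np.ndarray
    cutoff: float

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.matrix)
        if self.matrix.shape != (n, n):
            raise ValueError("contact matrix must be square")

    def __len__(self) -> int:
        return len(self.matrix)


@dataclass
class SpectralFingerprint:
    """Per-residue eigenvalue assignment of a contact matrix.

    ``assigned`` holds one eigenvalue per residue; ``spectrum`` is the full
    eigenvalue spectrum in descending order; ``n_nonpositive`` counts the
    eigenvalues that were ≤ 0 (clamped out of the assignment).
    """

    assigned: np.ndarray
    spectrum: np.ndarray
    n_nonpositive: int = 0
    chain_id: str | None = None
    contact_vectors: np.ndarray | None = None  # R = √D Uᵀ (clamped), rows by λ

    def __post_init__(self) -> None:
        self.assigned = np.asarray(self.assigned, dtype=float)
        self.spectrum = np.asarray(self.spectrum, dtype=float)
        if len(self.assigned) != len(self.spectrum):
            raise ValueError("one assignment per residue expected")

    def __len__(self) -> int:
        return len(self.assigned)


def contact_matrix(chain: CalphaChain, cutoff: float) -> ContactMatrix:
    """Build the smooth contact matrix of a chain at cutoff κ (Å).

    Entries decay linearly from 1 at zero distance to 0 at κ and vanish at
    and beyond κ; the diagonal is exactly 1.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n = len(chain)
    if n == 1:
        return ContactMatrix(np.ones((1, 1)), cutoff)
    d = squareform(pdist(chain.coords))
    C = np.where(d < cutoff, 1.0 - d / cutoff, 0.0)
    np.fill_diagonal(C, 1.0)
    return ContactMatrix(C, cutoff)


def spectral_fingerprint(C: ContactMatrix) -> SpectralFingerprint:
    """Assign each residue the eigenvalue of its nearest eigenspace.

    The contact matrix is factored as C = U D Uᵀ and R = √D Uᵀ is formed
    with eigenvalues clamped at zero inside the square root.  Residue i is
    assigned the λ_p (over strictly positive eigenvalues only) whose row of
    R carries the largest magnitude in column i; ties go to the larger
    eigenvalue.  Unlike a principal-component truncation, small positive
    eigenvalues participate fully in the assignment.

    Raises if no eigenvalue is positive (no assignment is possible).
    """
    w, U = np.linalg.eigh(C.matrix)
    order = np.argsort(w)[::-1]  # descending
    w = w[order]
    U = U[:, order]
    n_nonpos = int(np.sum(w <= 0))
    if n_nonpos == len(w):
        raise ValueError("contact matrix has no positive eigenvalue; cannot assign")
    if n_nonpos:
        logger.warning(
            "contact matrix (cutoff %.3g) has %d non-positive eigenvalues; "
            "clamped to 0 and excluded from assignment",
            C.cutoff,
            n_nonpos,
        )
    R = np.sqrt(np.clip(w, 0.0, None))[:, None] * U.T  # row p = √λ_p u_pᵀ
    pos = w > 0
    absR = np.abs(R[pos])
    # rows are in descending-λ order, so argmax resolves |R| ties toward the
    # larger eigenvalue
    winners = np.argmax(absR, axis=0)
    assigned = w[pos][winners]
    return SpectralFingerprint(
        assigned=assigned, spectrum=w, n_nonpositive=n_nonpos, contact_vectors=R
    )


def fingerprint_chain(chain: CalphaChain, cutoff: float) -> SpectralFingerprint:
    """Convenience: contact matrix + eigenvalue assignment in one call."""
    fp = spectral_fingerprint(contact_matrix(chain, cutoff))
    fp.chain_id = chain.chain_id
    return fp


def write_fingerprint(fp: SpectralFingerprint, destination: str | IO[str]) -> None:
    """Write a fingerprint as ``chain_id, residue_index, assigned_eigenvalue``."""
    cid = fp.chain_id or ""
    lines = [
        f"{cid},{i},{lam:.12g}" for i, lam in enumerate(fp.assigned)
    ]
    text = "\n".join(lines) + "\n"
    if isinstance(destination, str):
        with open(destination, "w") as fh:
            fh.write(text)
    else:
        destination.write(text)
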