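"""Cα traces: PDB input/output, NMR ensemble statistics and synthetic families.

A protein chain is reduced to the ordered coordinates of its alpha-carbon
(Cα) atoms, one per residue, together with the per-residue crystallographic
B-factors.  Everything downstream (contact matrices, spectral fingerprints,
alignment) consumes this representation and nothing else, so this module is
the only place that touches the PDB format.

The synthetic-family generator produces labelled sets of realistic Cα traces
(self-avoiding walks with backbone-like 3.8 Å spacing) so the whole pipeline,
including the parameter-sweep and perturbation experiments, runs with no
external structure downloads.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Literal, Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException, PDBConstructionWarning

logger = logging.getLogger(__name__)

__all__ = [
    "CalphaChain",
    "EnsembleStats",
    "PDBFormatError",
    "read_calpha_trace",
    "write_calpha_pdb",
    "ensemble_stats",
    "generate_synthetic_family",
    "read_family_labels",
    "write_family_labels",
]


class PDBFormatError(ValueError):
    """Raised for malformed or unusable PDB input."""


@dataclass
class CalphaChain:
    """One protein chain as an ordered Cα trace.

    Parameters
    ----------
    chain_id:
        Identifier of the chain (PDB chain letter, or any label).
    coords:
        ``(n, 3)`` array of Cα coordinates in Å, one row per residue, in
        backbone order.
    bfactors:
        ``(n,)`` array of non-negative B-factors in Å².
    family_id:
        Optional family label used as classification ground truth.
    """

    chain_id: str
    coords: np.ndarray
    bfactors: np.ndarray
    family_id: str | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.bfactors = np.asarray(self.bfactors, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (n, 3) array")
        if len(self.coords) < 1:
            raise ValueError("a chain needs at least one residue")
        if self.bfactors.shape != (len(self.coords),):
            raise ValueError("bfactors must have one entry per residue")
        if np.any(self.bfactors < 0):
            raise ValueError("B-factors must be non-negative")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.coords)


@dataclass
class EnsembleStats:
    """Per-residue, per-axis sample means and variances over NMR models.

    ``mean`` and ``variance`` are ``(n, 3)`` arrays (x, y, z columns);
    variances use the (n−1)-denominator sample estimator.
    """

    mean: np.ndarray
    variance: np.ndarray
    n_models: int = field(default=2)

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.variance = np.asarray(self.variance, dtype=float)
        if self.mean.shape != self.variance.shape or self.mean.ndim != 2:
            raise ValueError("mean and variance must be matching (n, 3) arrays")
        if np.any(self.variance < 0):
            raise ValueError("variances must be non-negative")
        if self.n_models < 2:
            raise ValueError("sample variances need at least 2 models")


def _select_ca_atom(residue):
    """Pick the Cα atom of a residue, resolving alternate locations.

    Keeps altloc ' ' (not disordered) directly; for disordered atoms the
    highest-occupancy conformer wins, ties broken alphabetically by altloc
    (so 'A' beats 'B'), giving one deterministic trace per chain.
    """
    if "CA" not in residue:
        return None
    atom = residue["CA"]
    if not atom.is_disordered():
        return atom
    children = atom.disordered_get_list()
    children = sorted(
        children, key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc())
    )
    return children[0]


def _chain_from_biopdb(bio_chain, chain_id: str) -> CalphaChain | None:
    coords: list[np.ndarray] = []
    bfactors: list[float] = []
    for residue in bio_chain:
        if residue.id[0] != " ":  # skip HETATM / water
            continue
        atom = _select_ca_atom(residue)
        if atom is None:
            logger.warning(
                "residue %s in chain %s has no CA atom; skipped", residue.id, chain_id
            )
            continue
        # PDB columns carry 3 decimals for coordinates and 2 for B-factors;
        # rounding undoes the parser's float32 storage noise
        coords.append(np.round(np.asarray(atom.get_coord(), dtype=float), 3))
        bfactors.append(max(round(float(atom.get_bfactor() or 0.0), 2), 0.0))
    if not coords:
        return None
    return CalphaChain(chain_id=chain_id, coords=np.array(coords), bfactors=np.array(bfactors))


def read_calpha_trace(
    source: str | IO[str],
    model_policy: Literal["first", "all", "index"] = "first",
    model_index: int = 0,
    chain_id: str | None = None,
) -> CalphaChain | list[CalphaChain]:
    """Read Cα traces from PDB text.

    Parameters
    ----------
    source:
        Path to a PDB file, or a text handle, or a string of PDB records.
    model_policy:
        ``"first"`` reads the first MODEL (or the sole implicit model),
        ``"all"`` returns one chain per MODEL block (NMR ensembles),
        ``"index"`` selects MODEL ``model_index`` (0-based).
    chain_id:
        Required when the file holds several chains; silent concatenation of
        chains is never performed.

    Returns
    -------
    A :class:`CalphaChain`, or a list of them when ``model_policy="all"``.

    Raises
    ------
    PDBFormatError
        If no Cα atoms are found, records are malformed (the underlying
        error names the offending line), or the chain is ambiguous.
    """
    if isinstance(source, str):
        if "\n" in source or source.lstrip().startswith(("ATOM", "MODEL", "HEADER")):
            handle: IO[str] = io.StringIO(source)
        else:
            handle = open(source)
    else:
        handle = source

    parser = PDBParser(PERMISSIVE=0, QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            structure = parser.get_structure("pdb", handle)
    except PDBConstructionException as exc:
        raise PDBFormatError(f"malformed PDB record: {exc}") from exc
    finally:
        if isinstance(source, str) and not isinstance(handle, io.StringIO):
            handle.close()

    models = list(structure)
    if not models:
        raise PDBFormatError("no models found in PDB input")

    def one_model(model) -> CalphaChain:
        chains = {c.id: c for c in model}
        if chain_id is not None:
            if chain_id not in chains:
                raise PDBFormatError(f"chain {chain_id!r} not present")
            picked = chains[chain_id]
        elif len(chains) == 1:
            picked = next(iter(chains.values()))
        else:
            raise PDBFormatError(
                f"file holds chains {sorted(chains)}; pass chain_id to select one"
            )
        trace = _chain_from_biopdb(picked, picked.id)
        if trace is None:
            raise PDBFormatError("no CA atoms found")
        return trace

    if model_policy == "first":
        return one_model(models[0])
    if model_policy == "index":
        if not 0 <= model_index < len(models):
            raise PDBFormatError(
                f"model_index {model_index} out of range (0..{len(models) - 1})"
            )
        return one_model(models[model_index])
    if model_policy == "all":
        return [one_model(m) for m in models]
    raise ValueError(f"unknown model_policy {model_policy!r}")


_ATOM_FMT = (
    "ATOM  {serial:>5d}  CA  ALA {chain}{resseq:>4d}    "
    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}           C  "
)


def write_calpha_pdb(
    models: CalphaChain | Sequence[CalphaChain], destination: str | IO[str]
) -> None:
    """Write one or several Cα traces as fixed-column PDB ATOM records.

    A sequence of chains is written as an NMR-style multi-MODEL file; all
    residues are emitted as alanine since only the backbone trace is kept.
    Coordinates are rounded to the PDB's 3 decimal places, B-factors to 2,
    so a write/read round trip is exact at that precision.
    """
    if isinstance(models, CalphaChain):
        models = [models]
    lines: list[str] = []
    multi = len(models) > 1
    for m_idx, chain in enumerate(models, start=1):
        if multi:
            lines.append(f"MODEL     {m_idx:>4d}")
        cid = (chain.chain_id or "A")[0]
        for r_idx, (xyz, b) in enumerate(zip(chain.coords, chain.bfactors), start=1):
            lines.append(
                _ATOM_FMT.format(
                    serial=r_idx,
                    chain=cid,
                    resseq=r_idx,
                    x=xyz[0],
                    y=xyz[1],
                    z=xyz[2],
                    occ=1.0,
                    b=b,
                )
            )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if isinstance(destination, str):
        with open(destination, "w") as fh:
            fh.write(text)
    else:
        destination.write(text)


def ensemble_stats(models: Sequence[CalphaChain]) -> EnsembleStats:
    """Per-residue, per-axis sample mean and variance over an NMR ensemble.

    Requires at least two models of identical length; variances use the
    unbiased (n−1) denominator.  With a single model the variance is
    undefined and an error is raised rather than silently reporting zero.
    """
    if len(models) < 2:
        raise ValueError("ensemble statistics require at least 2 models")
    n = len(models[0])
    if any(len(m) != n for m in models):
        raise ValueError("all ensemble models must have the same length")
    stack = np.stack([m.coords for m in models])  # (k, n, 3)
    mean = stack.mean(axis=0)
    variance = stack.var(axis=0, ddof=1)
    # coinciding models must give the shared value and exactly zero spread,
    # not rounding dust
    same = np.all(stack == stack[0], axis=0)
    mean[same] = stack[0][same]
    variance[same] = 0.0
    return EnsembleStats(mean=mean, variance=variance, n_models=len(models))


_STEP = 3.8  # consecutive Cα spacing, Å
_EXCLUSION = 4.0  # minimum distance between non-consecutive residues, Å


def _self_avoiding_walk(length: int, rng: np.random.Generator) -> np.ndarray:
    """3D walk with 3.8 Å steps; directions re-drawn while any non-consecutive
    pair would come closer than 4 Å. Restarts the walk on persistent failure."""
    while True:
        pts = np.zeros((length, 3))
        ok = True
        for i in range(1, length):
            for _ in range(500):
                v = rng.normal(size=3)
                v *= _STEP / np.linalg.norm(v)
                cand = pts[i - 1] + v
                if i < 2 or np.min(
                    np.linalg.norm(pts[: i - 1] - cand, axis=1)
                ) >= _EXCLUSION:
                    pts[i] = cand
                    break
            else:
                ok = False
                break
        if ok:
            return pts


def generate_synthetic_family(
    n_members: int,
    length: int,
    template_seed: int,
    jitter_sd: float,
    member_seed: int,
    family_id: str | None = None,
) -> list[CalphaChain]:
    """Generate a labelled synthetic family of Cα traces.

    A template trace is drawn from ``template_seed`` as a self-avoiding walk
    with backbone-like geometry; each member perturbs every coordinate with
    independent N(0, jitter_sd²) noise drawn from a stream derived from
    ``(member_seed, member index)``, so the set is fully reproducible and
    invariant to the order members are materialised in.  B-factors are
    positive, drawn once per template (uniform 20–60 Å², the mid range of
    crystallographic values), and shared by all members.
    """
    if n_members < 1:
        raise ValueError("n_members must be >= 1")
    if length < 2:
        raise ValueError("length must be >= 2")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be non-negative")
    fam = family_id if family_id is not None else f"fam{template_seed}"
    t_rng = np.random.default_rng(template_seed)
    template = _self_avoiding_walk(length, t_rng)
    bfactors = t_rng.uniform(20.0, 60.0, size=length)
    members = []
    for k in range(n_members):
        m_rng = np.random.default_rng([member_seed, k])
        noise = m_rng.normal(scale=jitter_sd, size=(length, 3)) if jitter_sd > 0 else 0.0
        members.append(
            CalphaChain(
                chain_id=f"{fam}_m{k}",
                coords=template + noise,
                bfactors=bfactors.copy(),
                family_id=fam,
            )
        )
    return members


def read_family_labels(source: str | IO[str]) -> dict[str, str]:
    """Read a two-column ``chain_id<TAB>family_id`` table."""
    if isinstance(source, str):
        with open(source) as fh:
            text = fh.read()
    else:
        text = source.read()
    labels: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"expected 'chain<TAB>family', got {line!r}")
        labels[parts[0]] = parts[1]
    return labels


def write_family_labels(labels: dict[str, str], destination: str | IO[str]) -> None:
    text = "".join(f"{c}\t{f}\n" for c, f in labels.items())
    if isinstance(destination, str):
        with open(destination, "w") as fh:
            fh.write(text)
    else:
        destination.write(text)
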