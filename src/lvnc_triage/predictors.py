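"""The four in-silico prediction channels.

Two channels are computed here from first principles:

* **Grantham physicochemical distance** between the reference and
  alternate residue, D(a,b) = rho * [alpha*(c_a-c_b)^2 + beta*(p_a-p_b)^2
  + gamma*(v_a-v_b)^2]^(1/2), where c is side-chain composition (atomic
  weight ratio of non-carbon elements), p polarity and v molecular volume.
  rho scales the mean of the 190 unordered residue-pair distances to 100.
  A distance above 100 is a radical (pathogenic) substitution; at or
  below 100 it is conservative (benign).
* **Conservation across species**: a position with zero substitutions
  among aligned orthologous residues is conserved (pathogenic); one or
  more substitutions make it not conserved (benign).

The other two channels, SIFT and PolyPhen-2, are externally produced
categorical labels; only normalization adapters live here.  Stop-gain
changes bypass all four channels (the prediction tools apply to missense
substitutions only).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path

import numpy as np

from .catalog import AMINO_ACIDS, ProteinChange

RESIDUES = tuple(sorted(AMINO_ACIDS))

_PROPS_SHA256 = "2fd63a2c55c6ece3c72480dec6414b7a0aa89f4e33e487e731510412da009a6d"
_CONST_SHA256 = "ece7a3227c90f51e0561092f7c4ec797aadb94216c8c0f401ce4ee2ed3d853b4"


class PredictorError(ValueError):
    pass


class Call(str, Enum):
    PATHOGENIC = "pathogenic"
    BENIGN = "benign"
    UNAVAILABLE = "unavailable"


@dataclass(frozen=True)
class ToolPrediction:
    tool: str
    raw_label: str
    call: Call


@dataclass(frozen=True)
class GranthamParameters:
    """Weights of the three property terms and the scale constant.

    ``rho`` normalizes the mean inter-residue distance to 100 so that the
    radical/conservative cutoff is interpretable on a fixed scale.
    """

    alpha: float
    beta: float
    gamma: float
    rho: float

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.gamma, self.rho) <= 0:
            raise PredictorError("Grantham parameters must be strictly positive")


def _read_asset(name: str, expected_sha256: str) -> str:
    ref = resources.files("lvnc_triage.data").joinpath(name)
    data = ref.read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != expected_sha256:
        raise PredictorError(
            f"checksum mismatch for embedded asset {name}: {digest}"
        )
    return data.decode("utf-8")


def load_amino_acid_properties() -> dict[str, tuple[float, float, float]]:
    """Load the checksummed (composition, polarity, volume) table."""
    text = _read_asset("grantham_properties.tsv", _PROPS_SHA256)
    table: dict[str, tuple[float, float, float]] = {}
    for line in text.splitlines()[1:]:
        residue, c, p, v = line.split("\t")
        table[residue] = (float(c), float(p), float(v))
    if set(table) != set(RESIDUES):
        raise PredictorError("property table must cover exactly the 20 canonical residues")
    return table


def load_grantham_parameters() -> GranthamParameters:
    text = _read_asset("grantham_constants.json", _CONST_SHA256)
    return GranthamParameters(**json.loads(text))


_DEFAULT_PROPS = load_amino_acid_properties()
_DEFAULT_PARAMS = load_grantham_parameters()


def grantham_distance(
    a: str,
    b: str,
    props: dict[str, tuple[float, float, float]] | None = None,
    params: GranthamParameters | None = None,
) -> float:
    """Physicochemical distance between residues ``a`` and ``b``.

    Symmetric, non-negative, zero exactly on the diagonal.  Full precision
    is returned; rounding to the nearest integer is a presentation choice
    made by callers.  Undefined for the stop symbol.
    """
    props = props if props is not None else _DEFAULT_PROPS
    params = params if params is not None else _DEFAULT_PARAMS
    try:
        ca, pa, va = props[a]
        cb, pb, vb = props[b]
    except KeyError as exc:
        raise PredictorError(f"Grantham distance undefined for residue {exc.args[0]!r}")
    return params.rho * math.sqrt(
        params.alpha * (ca - cb) ** 2
        + params.beta * (pa - pb) ** 2
        + params.gamma * (va - vb) ** 2
    )


def build_grantham_matrix(
    props: dict[str, tuple[float, float, float]] | None = None,
    params: GranthamParameters | None = None,
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Full 20x20 distance matrix (symmetric, zero diagonal).

    Returns the matrix and the residue ordering of its axes.  The mean of
    the 190 unordered off-diagonal distances sits at 100 (within 1) by the
    normalization built into ``rho``.
    """
    props = props if props is not None else _DEFAULT_PROPS
    if set(props) != set(RESIDUES):
        raise PredictorError("incomplete property table")
    n = len(RESIDUES)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = grantham_distance(RESIDUES[i], RESIDUES[j], props, params)
            mat[i, j] = mat[j, i] = d
    return mat, RESIDUES


def grantham_call(score: float, cutoff: float = 100.0) -> ToolPrediction:
    """Radical (pathogenic) iff the distance strictly exceeds the cutoff.

    A score exactly at the cutoff is called conservative/benign: pathogenic
    requires strict excess.
    """
    if not math.isfinite(score) or score < 0:
        raise PredictorError(f"invalid Grantham score {score!r}")
    call = Call.PATHOGENIC if score > cutoff else Call.BENIGN
    return ToolPrediction(tool="grantham", raw_label=f"{score:.6g}", call=call)


def grantham_prediction(change: ProteinChange, cutoff: float = 100.0) -> ToolPrediction:
    """Grantham channel for a protein change; unavailable for stop gains."""
    if change.is_stop_gain:
        return ToolPrediction(tool="grantham", raw_label="", call=Call.UNAVAILABLE)
    score = grantham_distance(change.ref_residue, change.alt_residue)
    return grantham_call(score, cutoff)


# ---------------------------------------------------------------------------
# Conservation across species
# ---------------------------------------------------------------------------

GAP = "-"


@dataclass(frozen=True)
class AlignmentColumn:
    """One column of a multi-species protein alignment."""

    reference_residue: str
    species_residues: dict[str, str]
    position: int = 0


def conservation_call(column: AlignmentColumn) -> ToolPrediction:
    """Conserved (pathogenic) iff zero substitutions among non-gap residues.

    Requires at least two usable residues (reference included); degenerate
    columns yield an ``unavailable`` call, never a vote.
    """
    if column.reference_residue not in AMINO_ACIDS:
        return ToolPrediction(tool="conservation", raw_label="", call=Call.UNAVAILABLE)
    usable = [r for r in column.species_residues.values() if r != GAP]
    if len(usable) + 1 < 2:
        return ToolPrediction(tool="conservation", raw_label="", call=Call.UNAVAILABLE)
    conserved = all(r == column.reference_residue for r in usable)
    return ToolPrediction(
        tool="conservation",
        raw_label="conserved" if conserved else "not_conserved",
        call=Call.PATHOGENIC if conserved else Call.BENIGN,
    )


def conservation_from_label(conserved: bool | None) -> ToolPrediction:
    """Adapter for a precomputed conserved yes/no annotation."""
    if conserved is None:
        return ToolPrediction(tool="conservation", raw_label="", call=Call.UNAVAILABLE)
    return ToolPrediction(
        tool="conservation",
        raw_label="conserved" if conserved else "not_conserved",
        call=Call.PATHOGENIC if conserved else Call.BENIGN,
    )


def read_alignment_fasta(path: str | Path, position: int, reference: str | None = None) -> AlignmentColumn:
    """Extract one column from a FASTA of aligned orthologous sequences.

    Sequences must have equal lengths; ``position`` is 1-based.  The first
    sequence is the reference unless ``reference`` names another header.
    """
    from Bio import SeqIO

    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise PredictorError(f"{path}: no sequences")
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise PredictorError(f"{path}: aligned sequences must have equal lengths")
    (length,) = lengths
    if not 1 <= position <= length:
        raise PredictorError(f"position {position} outside alignment of length {length}")
    ref_id = reference if reference is not None else next(iter(seqs))
    if ref_id not in seqs:
        raise PredictorError(f"reference species {ref_id!r} not in alignment")
    idx = position - 1
    return AlignmentColumn(
        reference_residue=seqs[ref_id][idx],
        species_residues={sp: s[idx] for sp, s in seqs.items() if sp != ref_id},
        position=position,
    )


# ---------------------------------------------------------------------------
# SIFT / PolyPhen-2 label adapters
# ---------------------------------------------------------------------------

_SIFT_MAP = {
    "damaging": Call.PATHOGENIC,
    "tolerated": Call.BENIGN,
    "tolerant": Call.BENIGN,
}

_POLYPHEN_MAP = {
    "probably damaging": Call.PATHOGENIC,
    "possibly damaging": Call.PATHOGENIC,
    "benign": Call.BENIGN,
}


def normalize_sift(label: str | None) -> ToolPrediction:
    """Map SIFT categorical labels to calls; anything unrecognised is unavailable."""
    raw = (label or "").strip()
    call = _SIFT_MAP.get(raw.lower(), Call.UNAVAILABLE)
    return ToolPrediction(tool="sift", raw_label=raw, call=call)


def normalize_polyphen(label: str | None) -> ToolPrediction:
    """Map PolyPhen-2 labels: probably/possibly damaging are pathogenic."""
    raw = (label or "").strip()
    call = _POLYPHEN_MAP.get(raw.lower().replace("_", " "), Call.UNAVAILABLE)
    return ToolPrediction(tool="polyphen2", raw_label=raw, call=call)
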