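"""Consensus pathogenicity classification from the four tool calls.

A missense variant is classified by agreement voting over the available
tool calls: pathogenic votes from >= 3 tools make it pathogenic, 1-2
make it a variant of uncertain significance (VUS), and zero pathogenic
votes make it benign — but benign additionally requires the full
four-tool panel, since a variant is never declared benign on partial
evidence (partial panels with no pathogenic votes become VUS, flagged).
Stop-gain variants are not analyzed (the tools apply to missense changes
only) and a variant whose residue could not be mapped onto the protein
isoforms is unclassifiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .catalog import VariantClass, VariantRecord
from .predictors import (
    Call,
    ToolPrediction,
    conservation_from_label,
    grantham_prediction,
    normalize_polyphen,
    normalize_sift,
)

N_TOOLS = 4


class Classification(str, Enum):
    PATHOGENIC = "pathogenic"
    VUS = "VUS"
    BENIGN = "benign"
    NOT_ANALYZED = "not_analyzed"
    UNCLASSIFIABLE = "unclassifiable"


class ConsensusError(ValueError):
    pass


@dataclass(frozen=True)
class ConsensusPolicy:
    """Voting thresholds; defaults implement the >=3-agreement rule."""

    pathogenic_min_votes: int = 3
    benign_requires_full_panel: bool = True

    def __post_init__(self) -> None:
        if not 1 <= self.pathogenic_min_votes <= N_TOOLS:
            raise ConsensusError("pathogenic_min_votes must be in 1..4")


DEFAULT_POLICY = ConsensusPolicy()


@dataclass(frozen=True)
class ConsensusClassification:
    variant_id: str
    n_tools_available: int
    n_pathogenic_votes: int
    classification: Classification
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not 0 <= self.n_pathogenic_votes <= self.n_tools_available <= N_TOOLS:
            raise ConsensusError(
                f"{self.variant_id}: inconsistent vote counts "
                f"{self.n_pathogenic_votes}/{self.n_tools_available}"
            )


def classify_votes(
    predictions: list[ToolPrediction],
    policy: ConsensusPolicy = DEFAULT_POLICY,
) -> tuple[int, int, Classification, frozenset[str]]:
    """Pure voting rule over a four-slot tool panel."""
    tools = [p.tool for p in predictions]
    if len(set(tools)) != len(tools):
        raise ConsensusError(f"duplicate tool slots in panel: {tools}")
    available = [p for p in predictions if p.call is not Call.UNAVAILABLE]
    n_avail = len(available)
    n_path = sum(p.call is Call.PATHOGENIC for p in available)
    flags: set[str] = set()
    if n_avail < N_TOOLS:
        flags.add("incomplete_tool_panel")
    if n_path >= policy.pathogenic_min_votes:
        cls = Classification.PATHOGENIC
    elif n_path >= 1:
        cls = Classification.VUS
    elif n_avail == N_TOOLS or not policy.benign_requires_full_panel:
        cls = Classification.BENIGN
    else:
        cls = Classification.VUS
    return n_avail, n_path, cls, frozenset(flags)


def predictions_for(variant: VariantRecord) -> list[ToolPrediction]:
    """Assemble the four-tool panel for one variant from catalog annotations.

    Grantham is computed from the residues (for cis compound records the
    maximum distance over the changes is used, the allele's most radical
    substitution); conservation uses the precomputed catalog label;
    SIFT/PolyPhen-2 labels pass through the normalization adapters.
    """
    if variant.variant_class is VariantClass.NONSENSE:
        return [
            ToolPrediction(tool=t, raw_label="", call=Call.UNAVAILABLE)
            for t in ("conservation", "grantham", "sift", "polyphen2")
        ]
    if variant.conserved is not None:
        cons = conservation_from_label(variant.conserved)
    else:
        cons = conservation_from_label(None)
    grantham_preds = [grantham_prediction(c) for c in variant.changes]
    grantham = max(
        grantham_preds,
        key=lambda p: float(p.raw_label) if p.raw_label else -1.0,
    )
    return [
        cons,
        grantham,
        normalize_sift(variant.tool_labels.get("sift")),
        normalize_polyphen(variant.tool_labels.get("polyphen2")),
    ]


def consensus_classify(
    variant: VariantRecord,
    predictions: list[ToolPrediction] | None = None,
    policy: ConsensusPolicy = DEFAULT_POLICY,
) -> ConsensusClassification:
    """Final classification of one catalog variant."""
    if variant.variant_class is VariantClass.NONSENSE:
        return ConsensusClassification(
            variant_id=variant.variant_id,
            n_tools_available=0,
            n_pathogenic_votes=0,
            classification=Classification.NOT_ANALYZED,
            flags=frozenset({"stop_gain"}),
        )
    if variant.residue_mismatch:
        return ConsensusClassification(
            variant_id=variant.variant_id,
            n_tools_available=0,
            n_pathogenic_votes=0,
            classification=Classification.UNCLASSIFIABLE,
            flags=frozenset({"residue_mismatch"}),
        )
    preds = predictions if predictions is not None else predictions_for(variant)
    n_avail, n_path, cls, flags = classify_votes(preds, policy)
    return ConsensusClassification(
        variant_id=variant.variant_id,
        n_tools_available=n_avail,
        n_pathogenic_votes=n_path,
        classification=cls,
        flags=flags,
    )


def classify_catalog(
    catalog, policy: ConsensusPolicy = DEFAULT_POLICY
) -> list[ConsensusClassification]:
    return [consensus_classify(rec, policy=policy) for rec in catalog]


def truncated_percent(count: int, denominator: int) -> int:
    """Integer percent by truncation toward zero (10/18 -> 55, not 56)."""
    if denominator <= 0:
        raise ConsensusError("denominator must be positive")
    return (100 * count) // denominator


def classification_fractions(
    classifications: list[ConsensusClassification],
    catalog=None,
    denominator: str = "analyzed",
) -> dict[Classification, tuple[int, int]]:
    """Per-class (count, truncated integer percent).

    Counting is per variant: a cis compound record contributes one count
    per protein change (requires ``catalog`` to recover multiplicities;
    without it every classification counts once).  ``denominator`` selects
    whether percents are over analyzed variants (excluding stop gains) or
    over all variants.
    """
    if not classifications:
        raise ConsensusError("empty classification list")
    weights = {rec.variant_id: rec.n_variants for rec in catalog} if catalog is not None else {}
    counts: dict[Classification, int] = {c: 0 for c in Classification}
    for cl in classifications:
        counts[cl.classification] += weights.get(cl.variant_id, 1)
    total = sum(counts.values())
    if denominator == "analyzed":
        denom = total - counts[Classification.NOT_ANALYZED]
    elif denominator == "all":
        denom = total
    else:
        raise ConsensusError(f"unknown denominator {denominator!r}")
    if denom <= 0:
        raise ConsensusError("no variants in denominator")
    return {
        cls: (n, truncated_percent(n, denom))
        for cls, n in counts.items()
        if n > 0
    }
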