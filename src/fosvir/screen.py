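"""Classify contigs as phage-derived from their per-gene virus-quotient
profile and phage hallmark genes.

Each predicted gene may carry a virus quotient (VQ): the phage specificity
of its orthologous group, 1 meaning the family is found only in phages.
Genuine phage contigs show a VQ profile dominated by values at or near 1,
and typically carry hallmark structural genes (terminase, tape measure
protein, capsid).  Selection in the original analysis was partly manual;
here it is replaced by declared, reproducible thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io import GeneAnnotation

#: hallmark flags that mark a contig viral on their own
HALLMARK_FLAGS = frozenset({"terminase", "tape_measure", "capsid"})


@dataclass(frozen=True)
class ScreenConfig:
    """Decision thresholds for the VQ-profile classifier.

    ``vq_high``: a gene counts as phage-specific when VQ >= this value.
    ``min_frac_vq_high`` (tau): minimum fraction of VQ-bearing genes that
    are phage-specific.  ``min_pog_genes`` (m): minimum number of
    VQ-bearing genes for the fraction to be trusted.
    """

    vq_high: float = 0.8
    min_frac_vq_high: float = 0.6
    min_pog_genes: int = 3


@dataclass(frozen=True)
class VQProfile:
    contig_id: str
    n_genes: int
    n_pog_genes: int
    frac_vq_high: float
    frac_defined: bool  # False when no gene carries a VQ
    signature_flags: dict = field(default_factory=dict)


def vq_profile(
    annotations: Sequence[GeneAnnotation], vq_high: float = 0.8
) -> VQProfile:
    """Summarise the VQ profile of one contig's annotations.

    Genes lacking a VQ are excluded from the ``frac_vq_high`` denominator;
    when no gene carries a VQ the fraction is reported as 0 with
    ``frac_defined`` False.
    """
    contig_ids = {a.contig_id for a in annotations}
    if len(contig_ids) > 1:
        raise ValueError(f"annotations span multiple contigs: {sorted(contig_ids)}")
    contig_id = contig_ids.pop() if contig_ids else ""
    with_vq = [a for a in annotations if a.vq is not None]
    n_high = sum(1 for a in with_vq if a.vq >= vq_high)
    flags: dict[str, int] = {}
    for a in annotations:
        for f in a.flags:
            flags[f] = flags.get(f, 0) + 1
    return VQProfile(
        contig_id=contig_id,
        n_genes=len(annotations),
        n_pog_genes=len(with_vq),
        frac_vq_high=(n_high / len(with_vq)) if with_vq else 0.0,
        frac_defined=bool(with_vq),
        signature_flags=flags,
    )


def classify_viral(
    profile: VQProfile, config: ScreenConfig = ScreenConfig()
) -> tuple[str, str]:
    """Decide viral / non-viral for one profile.

    A contig is viral when its VQ evidence passes both thresholds
    (inclusive comparisons) or when it carries at least one hallmark
    structural gene.  Returns (decision, rationale); the rationale lists
    every triggered rule.
    """
    reasons = []
    if (
        profile.frac_defined
        and profile.frac_vq_high >= config.min_frac_vq_high
        and profile.n_pog_genes >= config.min_pog_genes
    ):
        reasons.append(
            f"vq_profile: {profile.frac_vq_high:.2f} of {profile.n_pog_genes} "
            f"POG genes have VQ >= {config.vq_high}"
        )
    hallmark = sorted(
        f for f, n in profile.signature_flags.items() if f in HALLMARK_FLAGS and n > 0
    )
    if hallmark:
        reasons.append("hallmark_genes: " + ",".join(hallmark))
    if reasons:
        return "viral", "; ".join(reasons)
    return "non-viral", "no rule triggered"


def screen_contigs(
    annotations_by_contig: dict[str, Sequence[GeneAnnotation]],
    config: ScreenConfig = ScreenConfig(),
) -> dict[str, tuple[str, str]]:
    """Classify a whole contig set; returns contig_id -> (decision, rationale)."""
    out = {}
    for cid in sorted(annotations_by_contig):
        prof = vq_profile(annotations_by_contig[cid], vq_high=config.vq_high)
        out[cid] = classify_viral(prof, config)
    return out


def group_annotations(
    annotations: Iterable[GeneAnnotation],
) -> dict[str, list[GeneAnnotation]]:
    """Bucket a flat annotation list by contig id."""
    grouped: dict[str, list[GeneAnnotation]] = {}
    for a in annotations:
        grouped.setdefault(a.contig_id, []).append(a)
    return grouped
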