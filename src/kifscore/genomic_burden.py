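"""Copy-number burden decomposition and tumor mutation burden.

The copy-number burden of a sample decomposes additively into three scales:

* focal score      — sum of binned log2 ratios over focal segments (segments
                     confined to one arm and shorter than a configurable
                     fraction of that arm, default 0.5);
* arm score        — binned overlap-weighted mean log2 ratio per arm, summed
                     over arms that are not part of a chromosome event;
* chromosome score — when both arms of a chromosome bin to the same nonzero
                     value, the event is counted once at the chromosome
                     level and its arms are excluded from the arm score.

Binning maps a log2 copy ratio onto {-2,-1,0,1,2}:
2 if ratio >= 1; 1 if 0.25 <= ratio < 1; 0 if -0.25 <= ratio < 0.25;
-1 if -1 <= ratio < -0.25; -2 if ratio < -1.

Arms are additionally called gain (mean > 0.25), loss (mean < -0.25) or
neutral.  All coordinates are 1-based inclusive (SEG convention); bases not
covered by any segment count as log2 = 0 in arm means, since masked segment
files omit neutral regions.

TMB is the count of nonsilent mutation calls per sample, optionally per
megabase of exome (default 38 Mb).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .io_core import NONSILENT_CLASSES

logger = logging.getLogger("kifscore")

__all__ = [
    "CnvBurden",
    "bin_log2",
    "focal_score",
    "arm_level_means",
    "arm_calls",
    "arm_chromosome_scores",
    "total_cnv_score",
    "compute_burden",
    "compute_tmb",
]


@dataclasses.dataclass
class CnvBurden:
    sample: str
    focal: int
    arm: int
    chromosome: int
    total: int
    arm_call: dict[str, str]  # "chr1p" -> gain/loss/neutral
    arm_mean: dict[str, float]


def bin_log2(ratio):
    """Bin log2 copy ratios onto integer scores in {-2,-1,0,1,2}.

    Boundaries are inclusive exactly as published: 1 -> 2, 0.25 -> 1,
    -0.25 -> 0, -1 -> -1.
    """
    arr = np.asarray(ratio, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("non-finite log2 ratio")
    out = np.select(
        [arr >= 1.0, arr >= 0.25, arr >= -0.25, arr >= -1.0],
        [2, 1, 0, -1],
        default=-2,
    )
    if np.isscalar(ratio) or np.ndim(ratio) == 0:
        return int(out)
    return out.astype(int)


def _overlap(seg_start, seg_end, arm_start, arm_end) -> int:
    """Overlap length of two 1-based inclusive intervals (0 if disjoint)."""
    return max(0, min(seg_end, arm_end) - max(seg_start, arm_start) + 1)


def _arm_table(arms: pd.DataFrame) -> pd.DataFrame:
    arms = arms.copy()
    arms["label"] = arms["chromosome"].astype(str) + arms["arm"]
    arms["length"] = arms["end"] - arms["start"] + 1
    return arms


def focal_score(segments: pd.DataFrame, arms: pd.DataFrame, focal_fraction: float = 0.5) -> int:
    """Sum of binned ratios over focal segments of one sample.

    A segment is focal when it overlaps exactly one arm and its length is
    below ``focal_fraction`` of that arm's length.  A segment overlapping no
    declared arm is a schema error.
    """
    arms = _arm_table(arms)
    score = 0
    for seg in segments.itertuples(index=False):
        chrom_arms = arms[arms["chromosome"] == str(seg.chromosome)]
        overlaps = [
            (a, _overlap(seg.start, seg.end, a.start, a.end))
            for a in chrom_arms.itertuples(index=False)
        ]
        overlaps = [(a, o) for a, o in overlaps if o > 0]
        if not overlaps:
            raise ValueError(
                f"segment {seg.chromosome}:{seg.start}-{seg.end} overlaps no declared arm"
            )
        if len(overlaps) > 1:
            continue  # spans the centromere: not focal
        arm, _ = overlaps[0]
        seg_len = seg.end - seg.start + 1
        if seg_len < focal_fraction * arm.length:
            score += bin_log2(seg.log2_ratio)
    return int(score)


def arm_level_means(segments: pd.DataFrame, arms: pd.DataFrame) -> pd.Series:
    """Overlap-length-weighted mean log2 ratio per arm (uncovered bases = 0).

    Indexed by arm label ("chr1p", ...); every declared arm appears.
    """
    arms = _arm_table(arms)
    sums = {label: 0.0 for label in arms["label"]}
    for seg in segments.itertuples(index=False):
        for a in arms[arms["chromosome"] == str(seg.chromosome)].itertuples(index=False):
            ov = _overlap(seg.start, seg.end, a.start, a.end)
            if ov:
                sums[a.label] += ov * seg.log2_ratio
    lengths = arms.set_index("label")["length"]
    return pd.Series({lbl: sums[lbl] / lengths[lbl] for lbl in lengths.index}, name="arm_mean")


def arm_calls(
    segments: pd.DataFrame, arms: pd.DataFrame, threshold: float = 0.25
) -> pd.DataFrame:
    """Gain/loss/neutral call per arm from the weighted mean log2 ratio."""
    means = arm_level_means(segments, arms)
    call = np.where(means > threshold, "gain", np.where(means < -threshold, "loss", "neutral"))
    return pd.DataFrame({"arm_mean": means, "call": call})


def arm_chromosome_scores(
    arm_means: pd.Series, arms: pd.DataFrame, arm_indicator_mode: bool = False
) -> tuple[int, int]:
    """Split binned arm values into arm-level and chromosome-level scores.

    When both arms of a chromosome bin to the same nonzero value the event
    is chromosome-level: it contributes its bin once to the chromosome score
    and the arms contribute nothing to the arm score (the additive
    decomposition attributes each event to exactly one scale).  Otherwise
    each nonzero arm bin accrues to the arm score; with
    ``arm_indicator_mode`` arms contribute their sign (+/-1) instead of the
    binned magnitude.
    """
    arms = _arm_table(arms)
    arm_score = 0
    chrom_score = 0
    for chrom, grp in arms.groupby("chromosome"):
        labels = grp["label"].tolist()
        missing = [lbl for lbl in labels if lbl not in arm_means.index]
        if missing:
            raise ValueError(f"chromosome {chrom} missing arm value(s): {missing}")
        bins = [bin_log2(arm_means[lbl]) for lbl in labels]
        if len(bins) == 2 and bins[0] == bins[1] and bins[0] != 0:
            chrom_score += bins[0]
        else:
            for b in bins:
                if b != 0:
                    arm_score += int(np.sign(b)) if arm_indicator_mode else b
    return int(arm_score), int(chrom_score)


def total_cnv_score(
    sample: str,
    segments: pd.DataFrame,
    arms: pd.DataFrame,
    focal_fraction: float = 0.5,
    arm_call_threshold: float = 0.25,
    arm_indicator_mode: bool = False,
) -> CnvBurden:
    """Full burden decomposition of one sample's segments."""
    focal = focal_score(segments, arms, focal_fraction)
    means = arm_level_means(segments, arms)
    arm_sc, chrom_sc = arm_chromosome_scores(means, arms, arm_indicator_mode)
    call = np.where(means > arm_call_threshold, "gain",
                    np.where(means < -arm_call_threshold, "loss", "neutral"))
    return CnvBurden(
        sample=sample,
        focal=focal,
        arm=arm_sc,
        chromosome=chrom_sc,
        total=focal + arm_sc + chrom_sc,
        arm_call=dict(zip(means.index, call)),
        arm_mean=means.to_dict(),
    )


def compute_burden(
    segments: pd.DataFrame,
    arms: pd.DataFrame,
    focal_fraction: float = 0.5,
    arm_call_threshold: float = 0.25,
    arm_indicator_mode: bool = False,
) -> pd.DataFrame:
    """Burden decomposition for every sample in a segment table.

    Returns one row per sample: focal/arm/chromosome/total scores plus one
    gain-loss call column per declared arm.
    """
    rows = []
    for sample, segs in segments.groupby("sample", sort=True):
        burden = total_cnv_score(
            str(sample), segs, arms, focal_fraction, arm_call_threshold, arm_indicator_mode
        )
        row = {"sample": burden.sample, "focal": burden.focal, "arm": burden.arm,
               "chromosome": burden.chromosome, "total": burden.total}
        row.update({f"call_{lbl}": c for lbl, c in burden.arm_call.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def compute_tmb(
    mutations: pd.DataFrame,
    nonsilent_classes: frozenset[str] | set[str] = NONSILENT_CLASSES,
    exome_size_mb: float = 38.0,
    sample_universe=None,
) -> pd.DataFrame:
    """Nonsilent mutation count and per-megabase TMB per sample.

    Records with an unrecognized classification are excluded with a warning.
    ``sample_universe`` adds zero-count rows for samples absent from the
    mutation table.
    """
    from .io_core import MAF_CLASSES

    known = mutations["variant_classification"].isin(MAF_CLASSES | set(nonsilent_classes))
    unknown = mutations.loc[~known, "variant_classification"].unique()
    if len(unknown):
        logger.warning("excluding unknown variant classification(s): %s", sorted(unknown))
        mutations = mutations[known]
    nonsilent = mutations[mutations["variant_classification"].isin(nonsilent_classes)]
    counts = nonsilent.groupby("sample").size()
    if sample_universe is not None:
        counts = counts.reindex(sample_universe, fill_value=0)
    counts.index.name = "sample"
    out = counts.rename("nonsilent_count").reset_index()
    out["tmb"] = out["nonsilent_count"] / exome_size_mb
    return out
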