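"""Length-normalized conservation scoring with a matched un-transcribed null.

Per-interval mean score = sum of covered per-base scores over the
transcript's exonic bases / number of covered bases.  Uncovered bases are
excluded from both numerator and denominator: scoring them as 0 would
conflate missing alignment data with neutrality.  Control regions are
length-matched fragments sampled from un-transcribed genomic space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree
from scipy import stats as sps

from .genome_io import GenomeAssembly, Interval, ScoreTrack, TranscriptRecord

log = logging.getLogger(__name__)


@dataclass
class IntervalScore:
    interval_id: str
    mean_score: float  # nan when no base is covered
    covered_fraction: float

    @property
    def defined(self) -> bool:
        return self.covered_fraction > 0


@dataclass
class ControlSamplerConfig:
    n_controls: int
    seed: int = 0
    min_len: int = 500
    max_len: int = 15000
    max_attempts_factor: int = 200
    max_n_fraction: float = 0.5  # reject gap placements mostly made of N

    def __post_init__(self) -> None:
        if not (0 < self.min_len <= self.max_len):
            raise ValueError("need 0 < min_len <= max_len")


@dataclass
class Ecdf:
    values: np.ndarray  # sorted
    fractions: np.ndarray  # nondecreasing, ends at 1.0

    def at(self, x: float) -> float:
        """Right-continuous empirical CDF evaluated at x."""
        return float(np.searchsorted(self.values, x, side="right") / len(self.values))


def interval_mean_score(
    intervals: list[TranscriptRecord], track: ScoreTrack
) -> list[IntervalScore]:
    """Mean conservation score over the covered exonic bases of each interval.

    Intervals with zero covered bases get mean nan and are flagged
    (``defined`` False); a count is logged.
    """
    out = []
    n_undefined = 0
    for rec in intervals:
        scores = track.scores[rec.chrom]
        covered = track.covered[rec.chrom]
        total = 0.0
        n_cov = 0
        n_bases = 0
        for b0, b1 in rec.blocks:
            mask = covered[b0:b1]
            total += float(scores[b0:b1][mask].sum())
            n_cov += int(mask.sum())
            n_bases += b1 - b0
        if n_cov == 0:
            out.append(IntervalScore(rec.transcript_id, float("nan"), 0.0))
            n_undefined += 1
        else:
            out.append(IntervalScore(rec.transcript_id, total / n_cov, n_cov / n_bases))
    if n_undefined:
        log.info("%d intervals had no covered base and were flagged", n_undefined)
    return out


def sample_untranscribed_controls(
    assembly: GenomeAssembly,
    excluded: dict[str, list[Interval]],
    cfg: ControlSamplerConfig,
) -> list[TranscriptRecord]:
    """Random length-matched fragments from un-transcribed genomic space.

    Each control lies wholly inside a gap of the excluded set; its length
    is uniform on [min_len, max_len], truncated to the gap.  Sampling is a
    seeded rejection scheme: fully reproducible for a fixed seed.
    """
    rng = np.random.default_rng(cfg.seed)
    gaps: list[tuple[str, int, int]] = []
    for chrom in assembly.chrom_names:
        length = assembly.chrom_lengths[chrom]
        merged = _merge(excluded.get(chrom, []))
        pos = 0
        for s, e in merged:
            if s - pos >= cfg.min_len:
                gaps.append((chrom, pos, s))
            pos = max(pos, e)
        if length - pos >= cfg.min_len:
            gaps.append((chrom, pos, length))
    if not gaps:
        raise ValueError(f"no un-transcribed gap of >= {cfg.min_len} bp available")
    weights = np.array([e - s for _, s, e in gaps], dtype=float)
    weights /= weights.sum()
    controls = []
    attempts = 0
    max_attempts = cfg.max_attempts_factor * cfg.n_controls
    while len(controls) < cfg.n_controls:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"control sampling stalled: placed {len(controls)} of {cfg.n_controls}"
            )
        chrom, gs, ge = gaps[rng.choice(len(gaps), p=weights)]
        max_len = min(cfg.max_len, ge - gs)
        length = int(rng.integers(cfg.min_len, max_len + 1))
        start = int(rng.integers(gs, ge - length + 1))
        if assembly.sequence is not None and chrom in assembly.sequence:
            frag = assembly.sequence[chrom][start : start + length]
            if frag.upper().count("N") > cfg.max_n_fraction * length:
                continue
        controls.append(
            TranscriptRecord(
                f"control_{len(controls):05d}", chrom, ".", [(start, start + length)],
                source="control",
            )
        )
    return controls


def _merge(intervals: list[Interval]) -> list[Interval]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def ecdf(values) -> Ecdf:
    """Standard right-continuous empirical CDF of finite values."""
    arr = np.asarray([v for v in np.ravel(values) if np.isfinite(v)], dtype=float)
    if arr.size == 0:
        raise ValueError("ecdf of an empty value set")
    arr.sort()
    fractions = np.arange(1, arr.size + 1) / arr.size
    return Ecdf(arr, fractions)


@dataclass
class ConservationComparison:
    group_means: dict[str, float]
    # (a, b) -> {"mean_diff": mean(a)-mean(b), "p_greater": one-sided MW p for a > b}
    pairwise: dict[tuple[str, str], dict[str, float]]
    ecdfs: dict[str, Ecdf] = field(default_factory=dict)

    def ordering(self) -> list[str]:
        """Group labels sorted by decreasing mean score."""
        return sorted(self.group_means, key=lambda g: -self.group_means[g])


def compare_conservation(
    groups: dict[str, list[IntervalScore]],
    min_covered_fraction: float = 0.2,
) -> ConservationComparison:
    """Group means, pairwise one-sided Mann-Whitney tests, and per-group ECDFs.

    Intervals with no covered base, or covered fraction below
    ``min_covered_fraction``, are dropped before comparison.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    cleaned: dict[str, np.ndarray] = {}
    for label, scores in groups.items():
        vals = np.array(
            [s.mean_score for s in scores
             if s.defined and s.covered_fraction >= min_covered_fraction]
        )
        if vals.size == 0:
            raise ValueError(f"group {label!r} has no scoreable interval")
        cleaned[label] = vals
    means = {label: float(v.mean()) for label, v in cleaned.items()}
    pairwise = {}
    labels = list(cleaned)
    for a in labels:
        for b in labels:
            if a == b:
                continue
            p = float(sps.mannwhitneyu(cleaned[a], cleaned[b],
                                       alternative="greater").pvalue)
            pairwise[(a, b)] = {"mean_diff": means[a] - means[b], "p_greater": p}
    ecdfs = {label: ecdf(v) for label, v in cleaned.items()}
    return ConservationComparison(means, pairwise, ecdfs)
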