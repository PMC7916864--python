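"""Run-of-homozygosity detection and F_ROH.

Detection slides a window of ``min_window_snps`` consecutive SNPs one SNP at
a time along each scaffold.  A window is called homozygous when its
heterozygote count does not exceed ``floor(error_rate * window)`` — with the
default window of 20 SNPs and error rate 0.01 the budget is zero, i.e. any
heterozygote breaks a window, which makes detection deliberately strict.
Missing calls are non-informative: they neither count as heterozygous nor
break a run.  Maximal unions of overlapping homozygous windows become
segments spanning the first to the last SNP of the union; segments shorter
than a base-pair threshold are discarded downstream.

F_ROH is the total length of segments at or above a length threshold divided
by the callable genome length L (e.g. 802 Mb of >10 Mb scaffolds in a
typical draft-assembly resequencing study).  F_ROH is non-increasing in the
threshold, so the usual 500 kb / 1 Mb / 2 Mb runs give decreasing values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, SampleMetadata

logger = logging.getLogger(__name__)

__all__ = ["RohParams", "ROHSegment", "FrohResult", "detect_roh", "detect_roh_all", "f_roh"]


@dataclass
class RohParams:
    min_window_snps: int = 20
    error_rate: float = 0.01
    window_step: int = 1
    min_length: int = 0            # bp; thresholds are usually applied in f_roh

    def __post_init__(self) -> None:
        if self.min_window_snps < 2:
            raise ValueError("window must span at least 2 SNPs")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error rate must be in [0, 0.5)")

    @property
    def het_budget(self) -> int:
        return int(np.floor(self.error_rate * self.min_window_snps))


@dataclass(frozen=True)
class ROHSegment:
    sample: str
    scaffold: str
    start: int
    end: int
    n_snps: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class FrohResult:
    sample: str
    threshold: int
    total_length: int
    n_segments: int
    froh: float


def detect_roh(
    gm: GenotypeMatrix, sample: str, params: RohParams | None = None
) -> list[ROHSegment]:
    """Detect ROH segments for one sample across all scaffolds."""
    params = params or RohParams()
    si = gm.sample_index(sample)
    w = params.min_window_snps
    budget = params.het_budget
    segments: list[ROHSegment] = []

    for scaf in pd.unique(gm.scaffolds):
        cols = np.flatnonzero(gm.scaffolds == scaf)
        if cols.size < w:
            logger.debug("scaffold %s has fewer SNPs than the window; skipped", scaf)
            continue
        d = gm.dosages[si, cols]
        pos = gm.positions[cols]
        het = (d == 1).astype(np.int64)
        cums = np.concatenate([[0], np.cumsum(het)])
        win_het = cums[w:] - cums[:-w]                    # het count per window start
        good = win_het <= budget
        starts = np.flatnonzero(good)[:: params.window_step]
        if starts.size == 0:
            continue
        cover = np.zeros(d.size + 1, dtype=np.int64)
        np.add.at(cover, starts, 1)
        np.add.at(cover, starts + w, -1)
        covered = np.cumsum(cover[:-1]) > 0
        # maximal runs of covered SNPs
        edges = np.diff(np.concatenate([[0], covered.astype(np.int8), [0]]))
        run_starts = np.flatnonzero(edges == 1)
        run_ends = np.flatnonzero(edges == -1) - 1
        for a, b in zip(run_starts, run_ends):
            n_snps = int(b - a + 1)
            seg = ROHSegment(sample, str(scaf), int(pos[a]), int(pos[b]), n_snps)
            if n_snps >= w and seg.length >= params.min_length:
                segments.append(seg)
    return segments


def detect_roh_all(
    gm: GenotypeMatrix, params: RohParams | None = None
) -> dict[str, list[ROHSegment]]:
    return {s: detect_roh(gm, s, params) for s in gm.samples}


def f_roh(
    segments: list[ROHSegment],
    callable_length: int,
    threshold: int,
    sample: str | None = None,
) -> FrohResult:
    """F_ROH: total length of segments >= ``threshold`` bp over callable length L."""
    if callable_length <= 0:
        raise ValueError("callable length must be positive")
    for s in segments:
        if s.length > callable_length:
            raise ValueError(f"segment {s} longer than the callable length")
    kept = [s for s in segments if s.length >= threshold]
    total = sum(s.length for s in kept)
    name = sample or (segments[0].sample if segments else "")
    return FrohResult(
        sample=name,
        threshold=threshold,
        total_length=total,
        n_segments=len(kept),
        froh=total / callable_length,
    )


def froh_table(
    gm: GenotypeMatrix,
    metadata: SampleMetadata,
    thresholds: list[int],
    params: RohParams | None = None,
    callable_length: int | None = None,
) -> pd.DataFrame:
    """Per-sample F_ROH at each threshold, with group labels (Table-2-style input)."""
    L = callable_length or gm.callable_length()
    all_segs = detect_roh_all(gm, params)
    rows = []
    for s, segs in all_segs.items():
        for thr in thresholds:
            r = f_roh(segs, L, thr, sample=s)
            rows.append(
                {
                    "sample": s,
                    "group": metadata.group_of(s),
                    "threshold_bp": thr,
                    "n_segments": r.n_segments,
                    "total_length_bp": r.total_length,
                    "froh": r.froh,
                }
            )
    return pd.DataFrame(rows)
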