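"""Marker selection and crossover calling from tetrad genotype matrices.

The input is a spores x markers allele-dosage matrix for one tetrad
(four spores) on one chromosome: haploid spores carry dosage 0/1
(diploid parent), diploid spores carry dosage 0-2 (tetraploid parent).

Calling proceeds in three steps:

1. :func:`select_markers` keeps only markers segregating in the clean
   heterozygous configuration — tetrad dosage sum 2 of 4 allele copies
   for diploid tetrads (2:2), or 2 or 6 of 8 for tetraploid tetrads
   (2:6 / 6:2) — which screens out genotyping errors and non-Mendelian
   events.
2. :func:`call_crossovers` scans adjacent kept markers for reciprocal
   exchanges: exactly two spores changing dosage in complementary
   directions while the other two are unchanged.  Non-reciprocal changes
   are logged as anomalies and skipped.
3. Adjacent calls closer than a spacing threshold (default 10 kb,
   measured between interval midpoints) are collapsed pairwise
   left-to-right, keeping the leftmost of each merged pair; merged-away
   calls stay in the output with status ``merged-away``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "CrossoverCall",
    "select_markers",
    "call_crossovers",
    "merge_adjacent_calls",
    "summarize_co",
    "DEFAULT_MIN_SPACING_BP",
]

logger = logging.getLogger(__name__)

DEFAULT_MIN_SPACING_BP = 10_000


@dataclass
class GenotypeMatrix:
    """Ordered marker dosages for the four spores of one tetrad.

    ``dosages`` has shape (n_markers, 4); positions are bp, strictly
    increasing within the chromosome.
    """

    chrom: str
    positions: np.ndarray
    dosages: np.ndarray
    ploidy: str = "disomic"
    marker_ids: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2 or self.dosages.shape[1] != 4:
            raise ValueError("dosages must have shape (n_markers, 4)")
        if len(self.positions) != self.dosages.shape[0]:
            raise ValueError("positions and dosages disagree on marker count")
        if len(self.positions) and np.any(np.diff(self.positions) <= 0):
            raise ValueError("marker positions must be strictly increasing")
        hi = 1 if self.ploidy == "disomic" else 2
        if self.ploidy not in ("disomic", "tetrasomic"):
            raise ValueError(f"unknown ploidy {self.ploidy!r}")
        if len(self.positions) and (self.dosages.min() < 0 or self.dosages.max() > hi):
            raise ValueError(f"dosages outside [0, {hi}] for {self.ploidy} spores")
        if self.marker_ids is None:
            self.marker_ids = [f"m{j}" for j in range(len(self.positions))]

    @property
    def n_markers(self) -> int:
        return len(self.positions)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.dosages, columns=[f"spore{k+1}" for k in range(4)]
        )
        df.insert(0, "pos", self.positions)
        df.insert(0, "chrom", self.chrom)
        df.insert(0, "marker", list(self.marker_ids))
        return df


@dataclass(frozen=True)
class CrossoverCall:
    """One called crossover: the half-open interval between the flanking
    kept markers and the reciprocal spore pair involved."""

    chrom: str
    start: int
    end: int
    spores: tuple[int, int]
    tetrad: int = 0
    status: str = "observed"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("crossover interval must have start < end")
        if self.spores[0] == self.spores[1]:
            raise ValueError("crossover spore pair must be distinct")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


def select_markers(matrix: GenotypeMatrix) -> tuple[GenotypeMatrix, float]:
    """Keep markers in the clean segregating configuration.

    Diploid tetrads: tetrad dosage sum equals 2 (2:2 segregation of 4
    haploid spores).  Tetraploid tetrads: sum equals 2 or 6 of the 8
    allele copies (2:6 or 6:2).  Returns the filtered matrix and the
    retention fraction; dosages are never altered, only rows dropped.
    """
    sums = matrix.dosages.sum(axis=1)
    if matrix.ploidy == "disomic":
        keep = sums == 2
    else:
        keep = (sums == 2) | (sums == 6)
    retained = float(keep.mean()) if len(sums) else 0.0
    if not keep.any():
        logger.warning(
            "no marker on %s passes the segregation filter", matrix.chrom
        )
    out = GenotypeMatrix(
        chrom=matrix.chrom,
        positions=matrix.positions[keep],
        dosages=matrix.dosages[keep],
        ploidy=matrix.ploidy,
        marker_ids=[m for m, k in zip(matrix.marker_ids, keep) if k],
    )
    return out, retained


def _reciprocal_pair(delta: np.ndarray) -> Optional[tuple[int, int]]:
    """Spore pair of a reciprocal +1/-1 exchange, or None."""
    up = np.nonzero(delta == 1)[0]
    down = np.nonzero(delta == -1)[0]
    still = np.nonzero(delta == 0)[0]
    if len(up) == 1 and len(down) == 1 and len(still) == 2:
        a, b = int(up[0]), int(down[0])
        return (min(a, b), max(a, b))
    return None


def call_crossovers(
    matrix: GenotypeMatrix,
    min_spacing_bp: int = DEFAULT_MIN_SPACING_BP,
    tetrad: int = 0,
) -> list[CrossoverCall]:
    """Call crossovers between adjacent kept markers of one tetrad.

    A crossover is a reciprocal exchange: exactly one spore's dosage
    rises by 1 and exactly one falls by 1 between adjacent markers, the
    other two unchanged.  Any other non-zero dosage change (e.g. shared
    by three spores, or a +/-2 jump) is logged and skipped.  Calls whose
    interval midpoints lie closer than ``min_spacing_bp`` are merged (see
    :func:`merge_adjacent_calls`); all calls are returned sorted by
    position, merged-away ones included with their status marked.
    """
    if matrix.n_markers < 2:
        return []
    deltas = np.diff(matrix.dosages.astype(int), axis=0)
    calls: list[CrossoverCall] = []
    for k in range(deltas.shape[0]):
        d = deltas[k]
        if not d.any():
            continue
        pair = _reciprocal_pair(d)
        if pair is None:
            logger.info(
                "non-reciprocal dosage change on %s between %d and %d: %s",
                matrix.chrom,
                matrix.positions[k],
                matrix.positions[k + 1],
                d.tolist(),
            )
            continue
        calls.append(
            CrossoverCall(
                chrom=matrix.chrom,
                start=int(matrix.positions[k]),
                end=int(matrix.positions[k + 1]),
                spores=pair,
                tetrad=tetrad,
            )
        )
    return merge_adjacent_calls(calls, min_spacing_bp)


def merge_adjacent_calls(
    calls: Sequence[CrossoverCall], min_spacing_bp: int = DEFAULT_MIN_SPACING_BP
) -> list[CrossoverCall]:
    """Collapse runs of closely spaced calls.

    Calls are sorted by midpoint; consecutive calls closer than
    ``min_spacing_bp`` (midpoint distance) form a run.  Within a run the
    calls are collapsed pairwise left-to-right, keeping the leftmost of
    each pair, so a run of k calls keeps ceil(k/2) — the same surviving
    count a right-to-left sweep would give.  Merged-away calls are
    retained with status ``merged-away``.
    """
    ordered = sorted(calls, key=lambda c: (c.chrom, c.midpoint, c.start))
    out: list[CrossoverCall] = []
    run: list[CrossoverCall] = []

    def flush() -> None:
        for i, c in enumerate(run):
            status = "observed" if i % 2 == 0 else "merged-away"
            out.append(
                CrossoverCall(
                    chrom=c.chrom, start=c.start, end=c.end,
                    spores=c.spores, tetrad=c.tetrad, status=status,
                )
            )
        run.clear()

    for c in ordered:
        if run and (
            c.chrom != run[-1].chrom
            or c.midpoint - run[-1].midpoint >= min_spacing_bp
        ):
            flush()
        run.append(c)
    flush()
    return out


def summarize_co(
    calls_by_tetrad: Sequence[Sequence[CrossoverCall]],
    expected: Optional[dict] = None,
    combine: bool = False,
) -> pd.DataFrame:
    """Per-chromosome observed crossover counts and means per meiosis.

    ``expected`` optionally maps chromosome name to the estimated
    crossover count from the interval-probability method; observed and
    estimated totals are reported in separate columns and summed into a
    ``combined`` column only when ``combine`` is set.
    """
    rows: dict[str, list[int]] = {}
    n_tetrads = len(calls_by_tetrad)
    for t, calls in enumerate(calls_by_tetrad):
        for c in calls:
            if c.status != "observed":
                continue
            rows.setdefault(c.chrom, [0] * n_tetrads)
            rows[c.chrom][t] += 1
    if expected:
        for chrom in expected:
            rows.setdefault(chrom, [0] * n_tetrads)
    records = []
    for chrom in sorted(rows):
        counts = rows[chrom]
        rec = {
            "chrom": chrom,
            "n_tetrads": n_tetrads,
            "observed_total": int(np.sum(counts)),
            "observed_mean": float(np.mean(counts)) if n_tetrads else 0.0,
        }
        if expected is not None:
            rec["estimated"] = float(expected.get(chrom, 0.0))
            if combine:
                rec["combined"] = rec["observed_mean"] + rec["estimated"]
        records.append(rec)
    cols = ["chrom", "n_tetrads", "observed_total", "observed_mean"]
    if expected is not None:
        cols.append("estimated")
        if combine:
            cols.append("combined")
    return pd.DataFrame(records, columns=cols)
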