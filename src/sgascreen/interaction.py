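"""Genetic-interaction scoring from normalized colony sizes.

A genetic interaction score (GIS) for a library gene is the log2 ratio of
its normalized double-mutant colony size in the query background to the
matched control background, pooled across biological replicates and
replicate spots: ``GIS = mean(log2 q) - mean(log2 c)`` (the log2 of the
geometric-mean ratio).  Negative scores indicate synthetic sickness,
positive scores suppression/alleviation.

Significance uses a two-sided Welch t-test on the log2 sizes; genes within
a linkage window of the query locus are excluded (double mutants there are
depleted by genetic linkage during the cross, not by interaction).  Hits
are genes with |GIS| beyond a threshold (default 0.15) and p below a cutoff
(default 0.1), both strict.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .plate_io import EMPTY, GeneAnnotation, LibraryLayout, PlateGrid, logger
from .normalize import NormalizationResult
from .overlap_stats import GeneSet, OverlapResult, fisher_overlap

#: Default thresholds for hit calling.
GIS_THRESHOLD = 0.15
P_THRESHOLD = 0.1
MAX_LINKAGE_DIST = 250_000
MIN_REPS = 2

#: Variance floor for degenerate (zero-variance) replicate sets.
VAR_FLOOR = 1e-12

HIT_NONE = "none"
HIT_POSITIVE = "positive"
HIT_NEGATIVE = "negative"

EXCL_NONE = "none"
EXCL_LINKED = "linked"
EXCL_INSUFFICIENT = "insufficient_reps"


@dataclass
class GeneMeasurement:
    """Pooled normalized sizes for one gene in one condition."""

    gene_id: str
    condition: str
    query_sizes: list[float] = field(default_factory=list)
    control_sizes: list[float] = field(default_factory=list)


@dataclass
class InteractionRecord:
    """Per-gene interaction score, significance, and classification."""

    gene_id: str
    condition: str
    gis: float | None
    p_value: float | None
    n_query_reps: int
    n_control_reps: int
    excluded: bool = False
    exclusion_reason: str = EXCL_NONE
    hit_class: str = HIT_NONE


# ---------------------------------------------------------------------------
# Collation
# ---------------------------------------------------------------------------


def collate_measurements(
    plates: Sequence[NormalizationResult | PlateGrid],
    layout: LibraryLayout,
) -> list[GeneMeasurement]:
    """Pool unmasked corrected sizes per gene and condition.

    Accepts normalized plates (``NormalizationResult``) or bare
    :class:`PlateGrid` objects.  Sizes are pooled across biological
    replicates and replicate spots; EMPTY positions are dropped.  Genes in
    the layout absent from all plates yield measurements with empty lists
    (flagged downstream as ``insufficient_reps``).
    """
    grids = [p.corrected if isinstance(p, NormalizationResult) else p
             for p in plates]
    conditions = sorted({g.condition for g in grids})
    pools: dict[tuple[str, str], GeneMeasurement] = {}
    for gene in layout.genes():
        for cond in conditions:
            pools[(gene, cond)] = GeneMeasurement(gene_id=gene, condition=cond)

    for grid in grids:
        unmasked = ~grid.mask
        for r in range(grid.n_rows):
            for c in range(grid.n_cols):
                if not unmasked[r, c]:
                    continue
                gene = layout.gene_at(grid.plate_id, r + 1, c + 1)
                if gene is None or gene == EMPTY:
                    continue
                m = pools[(gene, grid.condition)]
                if grid.background == "query":
                    m.query_sizes.append(float(grid.size[r, c]))
                elif grid.background == "control":
                    m.control_sizes.append(float(grid.size[r, c]))
                else:
                    raise ValueError(
                        f"plate {grid.plate_id}: unknown background "
                        f"{grid.background!r}"
                    )
    return [pools[k] for k in sorted(pools)]


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------


def compute_gis(m: GeneMeasurement, min_reps: int = MIN_REPS) -> float:
    """GIS = mean(log2 query sizes) - mean(log2 control sizes).

    Raises ValueError when either side has fewer than ``min_reps`` sizes.
    """
    if len(m.query_sizes) < min_reps or len(m.control_sizes) < min_reps:
        raise ValueError(
            f"{m.gene_id}: insufficient replicates "
            f"({len(m.query_sizes)} query, {len(m.control_sizes)} control)"
        )
    q = np.log2(np.asarray(m.query_sizes, float))
    c = np.log2(np.asarray(m.control_sizes, float))
    return float(q.mean() - c.mean())


def welch_log2_pvalue(
    query_sizes: Sequence[float],
    control_sizes: Sequence[float],
    var_floor: float = VAR_FLOOR,
) -> float:
    """Two-sided Welch t-test p-value on log2-transformed sizes.

    Uses Welch-Satterthwaite degrees of freedom.  Sample variances are
    floored at ``var_floor`` so degenerate zero-variance replicate sets
    still yield a p-value (p = 1 when the means also coincide, near 0 when
    they are separated).
    """
    x = np.log2(np.asarray(query_sizes, float))
    y = np.log2(np.asarray(control_sizes, float))
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 sizes per side for a p-value")
    v1 = max(float(np.var(x, ddof=1)), var_floor)
    v2 = max(float(np.var(y, ddof=1)), var_floor)
    if np.var(x, ddof=1) < var_floor or np.var(y, ddof=1) < var_floor:
        logger.debug("zero-variance side floored at %g", var_floor)
    se2 = v1 / n1 + v2 / n2
    t = (float(x.mean()) - float(y.mean())) / math.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    return float(2.0 * stats.t.sf(abs(t), df))


def interaction_pvalue(m: GeneMeasurement, min_reps: int = MIN_REPS) -> float:
    """Welch p-value for one gene's pooled query vs control log2 sizes."""
    if len(m.query_sizes) < min_reps or len(m.control_sizes) < min_reps:
        raise ValueError(f"{m.gene_id}: insufficient replicates")
    return welch_log2_pvalue(m.query_sizes, m.control_sizes)


def score_measurements(
    measurements: Iterable[GeneMeasurement],
    min_reps: int = MIN_REPS,
) -> list[InteractionRecord]:
    """Score every gene; genes with too few replicates are excluded."""
    records = []
    for m in measurements:
        nq, nc = len(m.query_sizes), len(m.control_sizes)
        if nq < min_reps or nc < min_reps:
            records.append(InteractionRecord(
                gene_id=m.gene_id, condition=m.condition, gis=None,
                p_value=None, n_query_reps=nq, n_control_reps=nc,
                excluded=True, exclusion_reason=EXCL_INSUFFICIENT,
            ))
            continue
        records.append(InteractionRecord(
            gene_id=m.gene_id, condition=m.condition,
            gis=compute_gis(m, min_reps),
            p_value=interaction_pvalue(m, min_reps),
            n_query_reps=nq, n_control_reps=nc,
        ))
    return records


# ---------------------------------------------------------------------------
# Linkage exclusion
# ---------------------------------------------------------------------------


def parse_locus(text: str) -> tuple[str, int, int]:
    """Parse ``chrom:start-end`` (1-based inclusive, commas tolerated)."""
    m = re.fullmatch(r"([\w.]+):([\d,]+)-([\d,]+)", text.strip())
    if not m:
        raise ValueError(f"cannot parse locus {text!r} (expected chrom:start-end)")
    start = int(m.group(2).replace(",", ""))
    end = int(m.group(3).replace(",", ""))
    if start > end:
        raise ValueError(f"locus {text!r}: start > end")
    return m.group(1), start, end


def interval_distance(
    a: tuple[int, int], b: tuple[int, int]
) -> int:
    """Distance between the closest endpoints of two intervals; 0 if they
    overlap or touch."""
    (a0, a1), (b0, b1) = a, b
    if b0 > a1:
        return b0 - a1
    if a0 > b1:
        return a0 - b1
    return 0


def exclude_linked(
    records: Iterable[InteractionRecord],
    query_locus: tuple[str, int, int],
    annotation: GeneAnnotation,
    max_dist: int = MAX_LINKAGE_DIST,
) -> list[InteractionRecord]:
    """Exclude genes physically linked to the query locus.

    A gene is excluded (reason ``linked``) iff it lies on the query
    chromosome and the distance between the two intervals (0 when they
    overlap) is strictly less than ``max_dist``.  Genes without coordinates
    are retained with a warning.
    """
    q_chrom, q_start, q_end = query_locus
    out = []
    n_unannotated = 0
    for rec in records:
        if rec.gene_id not in annotation:
            n_unannotated += 1
            out.append(rec)
            continue
        chrom, start, end = annotation.locus(rec.gene_id)
        if chrom == q_chrom and interval_distance(
            (q_start, q_end), (start, end)
        ) < max_dist:
            rec = InteractionRecord(
                gene_id=rec.gene_id, condition=rec.condition, gis=rec.gis,
                p_value=rec.p_value, n_query_reps=rec.n_query_reps,
                n_control_reps=rec.n_control_reps, excluded=True,
                exclusion_reason=EXCL_LINKED, hit_class=HIT_NONE,
            )
        out.append(rec)
    if n_unannotated:
        logger.warning("%d scored genes lack coordinates; retained",
                       n_unannotated)
    return out


# ---------------------------------------------------------------------------
# Hit calling and condition comparison
# ---------------------------------------------------------------------------


def call_hits(
    records: Iterable[InteractionRecord],
    gis_threshold: float = GIS_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
) -> list[InteractionRecord]:
    """Classify each scored record as a positive/negative hit or none.

    Both thresholds are strict: a hit needs ``|GIS| > gis_threshold`` and
    ``p < p_threshold``.  Excluded records are always ``none``.
    """
    out = []
    for rec in records:
        hit = HIT_NONE
        if not rec.excluded and rec.gis is not None and rec.p_value is not None:
            if rec.p_value < p_threshold:
                if rec.gis > gis_threshold:
                    hit = HIT_POSITIVE
                elif rec.gis < -gis_threshold:
                    hit = HIT_NEGATIVE
        rec.hit_class = hit
        out.append(rec)
    return out


@dataclass
class ConditionComparison:
    """Shared hits between two conditions with Fisher overlap statistics."""

    condition_a: str
    condition_b: str
    background_genes: set[str]
    positive_a: set[str]
    positive_b: set[str]
    negative_a: set[str]
    negative_b: set[str]
    shared_positive: set[str]
    shared_negative: set[str]
    fisher_positive: OverlapResult
    fisher_negative: OverlapResult


def compare_conditions(
    records_a: Sequence[InteractionRecord],
    records_b: Sequence[InteractionRecord],
) -> ConditionComparison:
    """Intersect hit sets between two conditions and test the overlaps.

    The background universe is the set of genes scored (not excluded) in
    both conditions; both positive-hit and negative-hit overlaps are tested
    with the one-sided hypergeometric (Fisher) test.
    """
    scored_a = {r.gene_id for r in records_a if not r.excluded and r.gis is not None}
    scored_b = {r.gene_id for r in records_b if not r.excluded and r.gis is not None}
    background = scored_a & scored_b
    if not background:
        raise ValueError("empty common background between conditions")

    def hits(records, klass):
        return {r.gene_id for r in records
                if r.hit_class == klass and r.gene_id in background}

    pos_a, pos_b = hits(records_a, HIT_POSITIVE), hits(records_b, HIT_POSITIVE)
    neg_a, neg_b = hits(records_a, HIT_NEGATIVE), hits(records_b, HIT_NEGATIVE)
    cond_a = records_a[0].condition if records_a else "A"
    cond_b = records_b[0].condition if records_b else "B"

    fisher_pos = fisher_overlap(
        GeneSet(f"positive_{cond_a}", pos_a),
        GeneSet(f"positive_{cond_b}", pos_b),
        background_n=len(background),
    )
    fisher_neg = fisher_overlap(
        GeneSet(f"negative_{cond_a}", neg_a),
        GeneSet(f"negative_{cond_b}", neg_b),
        background_n=len(background),
    )
    return ConditionComparison(
        condition_a=cond_a, condition_b=cond_b, background_genes=background,
        positive_a=pos_a, positive_b=pos_b, negative_a=neg_a, negative_b=neg_b,
        shared_positive=pos_a & pos_b, shared_negative=neg_a & neg_b,
        fisher_positive=fisher_pos, fisher_negative=fisher_neg,
    )
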