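"""Classification of Polycomb target genes.

Three layered calls:

1. differential up-regulation from replicated fold changes via the rank
   product statistic with a permutation-based pfp (proportion of false
   positives), gated by a geometric-mean fold-change threshold;
2. promoter mark positivity from scaled coverage around the TSS relative to
   both genomic background and a depleted (knockout) condition;
3. set algebra combining the two into responsive / indirect / nonresponsive
   classes, plus timing (early vs late) and rescue sub-classifications that
   rerun the same differential rule on other contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CoverageTrack

__all__ = [
    "PromoterSignalSet",
    "TimecourseMatrix",
    "RankProductResult",
    "DifferentialRule",
    "rank_product",
    "call_differential",
    "promoter_enrichment",
    "classify_targets",
    "normalize_timecourse",
    "classify_early_late",
    "tss_density_profile",
    "classify_rescue",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class PromoterSignalSet:
    """Per-condition coverage tracks with scaling factors and annotation.

    ``scaling`` multiplies raw coverage before any comparison (the analogue
    of applying a per-condition coefficient to down-sampled read counts).
    ``annotation`` must carry columns chrom, tss0 (0-based), strand indexed
    by gene_id.
    """

    tracks: dict[str, CoverageTrack]
    scaling: dict[str, float]
    annotation: pd.DataFrame

    def __post_init__(self):
        for cond in self.tracks:
            self.scaling.setdefault(cond, 1.0)
        if any(f <= 0 for f in self.scaling.values()):
            raise ValueError("scaling factors must be > 0")

    def scaled_mean(self, cond: str, contig: str, start: int, end: int) -> float:
        return self.scaling[cond] * self.tracks[cond].mean(contig, start, end)

    def scaled_binned(self, cond, contig, start, end, bin_bp) -> np.ndarray:
        return self.scaling[cond] * self.tracks[cond].binned(contig, start, end, bin_bp)

    def background(self, cond: str) -> float:
        """Genome-wide mean scaled coverage (gaps count as zero)."""
        track = self.tracks[cond]
        return self.scaling[cond] * track.total_mass() / track.total_span()


class TimecourseMatrix:
    """genes x (timepoint, replicate) log2 expression.

    Columns follow the ``t{timepoint}_r{replicate}`` convention.
    """

    def __init__(self, data: pd.DataFrame):
        for col in data.columns:
            self._parse(col)
        self.data = data
        if 0 not in self.timepoints():
            raise ValueError("timepoint 0 must be present")

    @staticmethod
    def _parse(col: str) -> tuple[float, int]:
        try:
            t, r = col.split("_r")
            return float(t.lstrip("t")), int(r)
        except Exception as exc:
            raise ValueError(f"bad time-course column name {col!r} "
                             f"(expected 't<timepoint>_r<replicate>')") from exc

    def timepoints(self) -> list[float]:
        return sorted({self._parse(c)[0] for c in self.data.columns})

    def replicates(self, timepoint) -> list[int]:
        return sorted(self._parse(c)[1] for c in self.data.columns
                      if self._parse(c)[0] == float(timepoint))

    def at(self, timepoint) -> pd.DataFrame:
        """Columns at one timepoint, replicate-ordered, renamed to r1, r2..."""
        reps = self.replicates(timepoint)
        if not reps:
            raise KeyError(f"timepoint {timepoint} not present")
        cols = {}
        for c in self.data.columns:
            t, r = self._parse(c)
            if t == float(timepoint):
                cols[r] = c
        sub = self.data[[cols[r] for r in reps]]
        sub.columns = [f"r{r}" for r in reps]
        return sub

    def log_fold_changes(self, timepoint, reference=0) -> pd.DataFrame:
        """Per-replicate log2 fold changes timepoint vs reference (paired)."""
        a = self.at(timepoint)
        b = self.at(reference)
        if list(a.columns) != list(b.columns):
            raise ValueError("replicate structure differs between timepoints")
        return a - b.values


# ---------------------------------------------------------------------------
# rank product
# ---------------------------------------------------------------------------

@dataclass
class RankProductResult:
    table: pd.DataFrame  # index gene, columns rp, pfp, rp_rank
    n_permutations: int


def _rp_from_ranks(ranks: np.ndarray) -> np.ndarray:
    # geometric mean of per-replicate ranks; log-space for stability
    return np.exp(np.log(ranks).mean(axis=1))


def rank_product(fold_changes: pd.DataFrame, B: int = 200,
                 seed: int | None = None) -> RankProductResult:
    """Rank product for up-regulation with permutation pfp.

    ``fold_changes``: genes x replicates, log2 fold changes; within each
    replicate the most up-regulated gene receives rank 1 (ties get the
    average rank).  RP is the geometric mean of per-replicate ranks; the
    permutation null shuffles each replicate's values independently across
    genes and the pfp of gene g is the expected number of null RP values at
    or below RP_g divided by g's rank among observed RPs.
    """
    if fold_changes.shape[1] < 2:
        raise ValueError("rank product needs k >= 2 replicates")
    if B < 1:
        raise ValueError("need at least 1 permutation")
    from scipy.stats import rankdata

    fc = fold_changes.to_numpy(dtype=float)
    n, k = fc.shape
    ranks = np.column_stack([rankdata(-fc[:, j]) for j in range(k)])
    rp = _rp_from_ranks(ranks)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(n)
    rp_sorted = np.sort(rp)
    for _ in range(B):
        perm_ranks = np.column_stack(
            [rng.permutation(n) + 1.0 for _ in range(k)])
        rp_null = np.sort(_rp_from_ranks(perm_ranks))
        # for each observed rp, count null values <= it
        exceed += np.searchsorted(rp_null, rp, side="right")
    expected_fp = exceed / B
    rp_rank = rankdata(rp, method="max")  # 1 = smallest RP = strongest up
    pfp = expected_fp / rp_rank
    table = pd.DataFrame(
        {"rp": rp, "pfp": pfp, "rp_rank": rp_rank}, index=fold_changes.index)
    return RankProductResult(table=table, n_permutations=B)


@dataclass(frozen=True)
class DifferentialRule:
    """Thresholds + permutation settings for an up-regulation call."""

    pfp_max: float = 0.15
    fc_min: float = 2.0
    B: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.pfp_max <= 0 or self.fc_min <= 0:
            raise ValueError("thresholds must be > 0")


def call_differential(rp: RankProductResult, fold_changes: pd.DataFrame,
                      pfp_max: float = 0.15, fc_min: float = 2.0) -> set:
    """Up-regulated genes: geometric-mean FC >= fc_min AND pfp <= pfp_max.

    ``fold_changes`` are per-replicate log2 values; the geometric-mean fold
    change on the linear scale is 2**mean(log2 FC).
    """
    if pfp_max <= 0 or fc_min <= 0:
        raise ValueError("thresholds must be > 0")
    geo_fc = np.exp2(fold_changes.mean(axis=1))
    ok = (geo_fc >= fc_min) & (rp.table["pfp"].reindex(fold_changes.index) <= pfp_max)
    return set(fold_changes.index[ok])


def call_up_regulated(fold_changes: pd.DataFrame, rule: DifferentialRule) -> set:
    rp = rank_product(fold_changes, B=rule.B, seed=rule.seed)
    return call_differential(rp, fold_changes, pfp_max=rule.pfp_max,
                             fc_min=rule.fc_min)


# ---------------------------------------------------------------------------
# promoter signal
# ---------------------------------------------------------------------------

def promoter_enrichment(signals: PromoterSignalSet, window_bp: int = 2000,
                        threshold_fold: float = 2.0, wt: str = "wt",
                        ko: str = "ko") -> pd.DataFrame:
    """Promoter mark score and positivity call per gene.

    Score = mean scaled wild-type coverage over [tss - w, tss + w).
    Positive iff score >= threshold_fold * genomic background AND
    score >= threshold_fold * the knockout promoter mean.  Windows running
    off the covered contig span are clipped and flagged.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    rows = []
    bg = signals.background(wt)
    for gene, ann in signals.annotation.iterrows():
        contig = ann["chrom"]
        tss0 = int(ann["tss0"])
        lo, hi = tss0 - window_bp, tss0 + window_bp
        clipped = False
        if contig in signals.tracks[wt].intervals:
            span_lo, span_hi = signals.tracks[wt].span(contig)
            if lo < span_lo or hi > span_hi:
                clipped = True
                lo = max(lo, span_lo)
                hi = min(hi, span_hi)
        if hi <= lo:
            rows.append((gene, 0.0, 0.0, False, True))
            continue
        score = signals.scaled_mean(wt, contig, lo, hi)
        ko_score = signals.scaled_mean(ko, contig, lo, hi) if ko in signals.tracks else 0.0
        positive = score >= threshold_fold * bg and score >= threshold_fold * ko_score
        rows.append((gene, score, ko_score, bool(positive), clipped))
    df = pd.DataFrame(rows, columns=["gene", "score", "ko_score", "positive",
                                     "clipped"]).set_index("gene")
    df.attrs["background"] = bg
    return df


def tss_density_profile(signals: PromoterSignalSet, gene_set,
                        window_bp: int = 5000, bin_bp: int = 100,
                        condition: str = "wt") -> np.ndarray:
    """Strand-oriented mean binned coverage around the TSS of a gene set.

    Bin 0 is window_bp upstream of the TSS; the array has 2*window_bp/bin_bp
    entries.  Minus-strand gene profiles are reversed so upstream is left.
    """
    genes = list(gene_set)
    if not genes:
        raise ValueError("empty gene set")
    if (2 * window_bp) % bin_bp != 0:
        raise ValueError("bin_bp must divide 2*window_bp")
    profiles = []
    for gene in genes:
        ann = signals.annotation.loc[gene]
        tss0 = int(ann["tss0"])
        prof = signals.scaled_binned(condition, ann["chrom"],
                                     tss0 - window_bp, tss0 + window_bp, bin_bp)
        if ann["strand"] == "-":
            prof = prof[::-1]
        profiles.append(prof)
    return np.mean(profiles, axis=0)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_targets(up_set, promoter_positive_set, all_genes):
    """Partition genes into responsive / indirect / nonresponsive / null."""
    all_genes = list(all_genes)
    up = set(up_set)
    pos = set(promoter_positive_set)
    universe = set(all_genes)
    if not up <= universe or not pos <= universe:
        raise ValueError("up/positive sets must be subsets of all_genes")
    responsive = up & pos
    indirect = up - pos
    nonresponsive = pos - up
    labels = {}
    for g in all_genes:
        if g in responsive:
            labels[g] = "responsive"
        elif g in indirect:
            labels[g] = "indirect"
        elif g in nonresponsive:
            labels[g] = "nonresponsive"
        else:
            labels[g] = "null"
    counts = {
        "responsive": len(responsive),
        "indirect": len(indirect),
        "nonresponsive": len(nonresponsive),
        "null": len(all_genes) - len(responsive) - len(indirect) - len(nonresponsive),
    }
    series = pd.Series(labels).reindex(all_genes)
    series.name = "class"
    return series, counts


def normalize_timecourse(tc: TimecourseMatrix) -> pd.DataFrame:
    """Linear-scale ratios to the time-0 value, per gene per replicate.

    Input is log2, so the ratio is 2**(x_t - x_0) for the matching replicate.
    """
    t0 = tc.at(0)
    out = {}
    for col in tc.data.columns:
        t, r = TimecourseMatrix._parse(col)
        ref = t0[f"r{r}"]
        out[col] = np.exp2(tc.data[col] - ref)
    return pd.DataFrame(out, index=tc.data.index)


def classify_early_late(tc: TimecourseMatrix, responsive_set, early_timepoint,
                        rule: DifferentialRule = DifferentialRule()) -> pd.Series:
    """Responsive genes already up at the early timepoint are 'early'.

    The same rank-product + fold-change rule used for the endpoint call is
    applied to the early-vs-0 contrast; responsive genes failing it are
    'late', non-responsive genes get 'NA'.
    """
    if float(early_timepoint) not in tc.timepoints():
        raise ValueError(f"timepoint {early_timepoint} not in time course")
    lfc = tc.log_fold_changes(early_timepoint)
    up_early = call_up_regulated(lfc, rule)
    labels = {}
    for g in tc.data.index:
        if g not in responsive_set:
            labels[g] = "NA"
        elif g in up_early:
            labels[g] = "early"
        else:
            labels[g] = "late"
    series = pd.Series(labels).reindex(tc.data.index)
    series.name = "timing"
    return series


def classify_rescue(expr_wt: pd.DataFrame, expr_rescue: pd.DataFrame,
                    responsive_set,
                    rule: DifferentialRule = DifferentialRule()) -> pd.Series:
    """Responsive genes still up in the rescue condition are 'non_rescued'.

    ``expr_wt`` and ``expr_rescue`` are genes x replicates log2 matrices with
    matched replicate columns.
    """
    if not expr_wt.index.equals(expr_rescue.index):
        raise ValueError("gene sets must match between conditions")
    lfc = expr_rescue - expr_wt.values
    still_up = call_up_regulated(lfc, rule)
    labels = {}
    for g in expr_wt.index:
        if g not in responsive_set:
            labels[g] = "NA"
        elif g in still_up:
            labels[g] = "non_rescued"
        else:
            labels[g] = "rescued"
    series = pd.Series(labels).reindex(expr_wt.index)
    series.name = "rescue"
    return series
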