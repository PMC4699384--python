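"""Synthetic inputs with the statistical structure the analyses assume.

Four generators cover the pipeline end to end:

* a tumor cohort (expression + copy number + right-censored disease-specific
  survival) in which hazard rises with a latent proliferation factor and
  falls with the proliferation-independent component of a marker transcript;
* an in-vitro growth experiment of (growth rate, enzyme, mark) triplets
  under control vs weakened enzyme-proliferation coupling;
* gene-level promoter mark signal plus expression time courses with planted
  responsive / indirect / nonresponsive classes, early/late timing, and a
  rescue condition;
* a genes x cells single-cell matrix with dye labels, a genotype assay
  channel, and deterministic vs stochastic activation classes.

Every generator takes a frozen config carrying its own seed and is
byte-reproducible.  Each returns a truth record sufficient to verify every
downstream classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .homeostasis import MarkKineticsParams, steady_state_mark
from .io import CoverageTrack
from .targets import PromoterSignalSet, TimecourseMatrix

__all__ = [
    "CohortConfig",
    "GrowthExperimentConfig",
    "TargetsConfig",
    "SingleCellConfig",
    "GeneClassSpec",
    "CohortDataset",
    "TargetDataset",
    "SingleCellDataset",
    "generate_cohort",
    "generate_growth_experiment",
    "generate_target_dataset",
    "generate_singlecell_dataset",
    "MARKER_GENE",
    "CONTROL_GENE",
]

MARKER_GENE = "MARKER"
CONTROL_GENE = "PROLIF_CTRL"  # pure proliferation readout, no independent effect
EXPR_BASELINE = 7.0           # arbitrary log2 offset for all transcripts


def _check_prob(name, value):
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must be in [0, 1], got {value}")


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortConfig:
    n_samples: int = 2000
    n_genes: int = 120
    n_prolif_genes: int = 54
    beta_prolif: float = 0.8
    beta_resid: float = -0.5
    cnv_loss_prob: float = 0.15
    cnv_gain_prob: float = 0.15
    cnv_effect: float = 0.8       # log2 expression shift per copy state
    noise_sd: float = 0.3
    censor_rate: float = 20.0     # administrative horizon: censor ~ U(0, rate)
    lost_arm_genes: tuple = ()
    baseline_hazard: float = 0.05
    seed: int = 0

    def __post_init__(self):
        for name in ("n_samples", "n_genes", "n_prolif_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_prolif_genes >= self.n_genes:
            raise ValueError("n_prolif_genes must be < n_genes")
        _check_prob("cnv_loss_prob", self.cnv_loss_prob)
        _check_prob("cnv_gain_prob", self.cnv_gain_prob)
        if self.cnv_loss_prob + self.cnv_gain_prob > 1:
            raise ValueError("cnv_loss_prob + cnv_gain_prob must be <= 1")
        if self.noise_sd < 0 or self.baseline_hazard <= 0:
            raise ValueError("noise_sd must be >= 0 and baseline_hazard > 0")


@dataclass
class CohortDataset:
    expression: pd.DataFrame   # genes x samples
    cnv: pd.DataFrame          # samples x genes
    clinical: pd.DataFrame     # indexed by sample_id: time, event, er_status
    truth: dict

    def __iter__(self):
        return iter((self.expression, self.cnv, self.clinical, self.truth))


def cohort_gene_ids(config: CohortConfig) -> list[str]:
    """Gene id layout: marker, proliferation control, proliferation set, fillers."""
    prolif = [f"PROLIF_{i:03d}" for i in range(config.n_prolif_genes)]
    n_fill = config.n_genes - config.n_prolif_genes - 2
    if n_fill < 0:
        raise ValueError("n_genes too small for marker + control + prolif set")
    fillers = [f"G_{i:04d}" for i in range(n_fill)]
    return [MARKER_GENE, CONTROL_GENE] + prolif + fillers


def generate_cohort(config: CohortConfig) -> CohortDataset:
    """Simulate the tumor cohort.

    Marker expression = P_s + cnv_effect * state + noise; the latent
    proliferation factor P_s is standard normal, realised in the
    proliferation genes with unit slope.  Survival times are exponential
    with hazard baseline_hazard * exp(beta_prolif * P_s + beta_resid * R_s),
    R_s being the marker's proliferation-independent component; censoring is
    an independent uniform administrative time on [0, censor_rate].
    """
    rng = np.random.default_rng(config.seed)
    genes = cohort_gene_ids(config)
    arm = set(config.lost_arm_genes)
    unknown = arm - set(genes)
    if unknown:
        raise ValueError(f"lost_arm_genes not in the gene layout: {sorted(unknown)}")
    n = config.n_samples
    samples = [f"S{i:04d}" for i in range(n)]

    P = rng.standard_normal(n)

    # copy-number states: arm genes share one carrier indicator per sample
    states = pd.DataFrame(0, index=samples, columns=genes, dtype=int)
    arm_carrier = rng.random(n) < config.cnv_loss_prob if arm else np.zeros(n, bool)
    for g in genes:
        if g in arm:
            states[g] = np.where(arm_carrier, -1, 0)
        else:
            u = rng.random(n)
            states[g] = np.where(
                u < config.cnv_loss_prob, -1,
                np.where(u < config.cnv_loss_prob + config.cnv_gain_prob, 1, 0))

    expr = pd.DataFrame(index=genes, columns=samples, dtype=float)
    noise = lambda: rng.normal(0.0, config.noise_sd, n)

    marker_noise = noise()
    R = config.cnv_effect * states[MARKER_GENE].to_numpy() + marker_noise
    expr.loc[MARKER_GENE] = EXPR_BASELINE + P + R
    expr.loc[CONTROL_GENE] = EXPR_BASELINE + P + noise()
    for g in genes:
        if g.startswith("PROLIF_") and g != CONTROL_GENE:
            expr.loc[g] = EXPR_BASELINE + P + noise()
        elif g not in (MARKER_GENE, CONTROL_GENE):
            expr.loc[g] = (EXPR_BASELINE
                           + config.cnv_effect * states[g].to_numpy() + noise())

    hazard = config.baseline_hazard * np.exp(
        config.beta_prolif * P + config.beta_resid * R)
    event_time = rng.exponential(1.0 / hazard)
    if config.censor_rate > 0:
        censor_time = rng.uniform(0.0, config.censor_rate, n)
    else:
        censor_time = np.full(n, np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    er_status = rng.random(n) < 0.75  # ER-positive majority, analysis filter only

    clinical = pd.DataFrame(
        {"time": time, "event": event,
         "er_status": np.where(er_status, "positive", "negative")},
        index=pd.Index(samples, name="sample_id"))

    truth = {
        "P": dict(zip(samples, P)),
        "R": dict(zip(samples, R)),
        "marker_gene": MARKER_GENE,
        "control_gene": CONTROL_GENE,
        "prolif_genes": [g for g in genes
                         if g.startswith("PROLIF_") and g != CONTROL_GENE],
        "lost_arm_genes": sorted(arm),
        "arm_carriers": [s for s, c in zip(samples, arm_carrier) if c],
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(config).items()},
    }
    return CohortDataset(expression=expr, cnv=states, clinical=clinical, truth=truth)


# ---------------------------------------------------------------------------
# growth experiment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrowthExperimentConfig:
    growth_rates: tuple = (0.01, 0.02, 0.04, 0.06, 0.08, 0.1)
    c0: float = 0.0
    c1: float = 40.0
    knockdown_c1: float = 10.0
    knockdown_c0: float = 0.5
    kinetics: MarkKineticsParams = field(default_factory=MarkKineticsParams)
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if any(g <= 0 for g in self.growth_rates):
            raise ValueError("growth rates must be > 0")
        if self.knockdown_c1 >= self.c1:
            raise ValueError("knockdown slope must be < control slope")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


def generate_growth_experiment(config: GrowthExperimentConfig) -> pd.DataFrame:
    """(condition, g, enzyme, mark) rows from the steady-state model.

    Enzyme follows the affine coupling of each arm; the mark is the
    steady-state occupancy; both readouts get mean-one lognormal
    multiplicative noise with the requested coefficient of variation.
    """
    rng = np.random.default_rng(config.seed)
    sigma = np.sqrt(np.log1p(config.noise_cv**2))

    def noisy(x):
        if sigma == 0:
            return x
        return x * rng.lognormal(-sigma**2 / 2, sigma)

    rows = []
    for condition, c0, c1 in (
        ("control", config.c0, config.c1),
        ("knockdown", config.knockdown_c0, config.knockdown_c1),
    ):
        for g in config.growth_rates:
            E = c0 + c1 * g
            params = MarkKineticsParams(
                alpha=config.kinetics.alpha, delta=config.kinetics.delta,
                growth_rate=g, enzyme=E)
            m = steady_state_mark(params)
            rows.append((condition, g, noisy(E), noisy(m)))
    return pd.DataFrame(rows, columns=["condition", "g", "enzyme", "mark"])


# ---------------------------------------------------------------------------
# target classification dataset
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TargetsConfig:
    n_genes: int = 400
    frac_responsive: float = 0.05
    frac_indirect: float = 0.025
    frac_nonresponsive: float = 0.3
    fraction_early: float = 0.25
    fraction_nonrescued: float = 0.25
    promoter_enrichment_high: float = 8.0
    promoter_enrichment_low: float = 4.0
    timepoints: tuple = (0.0, 5.0, 10.0)
    fold_change_up: float = 2.0   # planted log2 effect
    k_replicates: int = 4
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_genes <= 0 or self.k_replicates < 2:
            raise ValueError("n_genes must be > 0 and k_replicates >= 2")
        total = self.frac_responsive + self.frac_indirect + self.frac_nonresponsive
        if total > 1.0 + 1e-12:
            raise ValueError("class fractions must sum to <= 1")
        for name in ("frac_responsive", "frac_indirect", "frac_nonresponsive",
                     "fraction_early", "fraction_nonrescued"):
            _check_prob(name, getattr(self, name))
        tp = self.timepoints
        if len(tp) < 2 or tp[0] != 0 or any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError("timepoints must be strictly increasing and start at 0")
        if self.promoter_enrichment_high < self.promoter_enrichment_low:
            raise ValueError("promoter_enrichment_high must be >= low")


@dataclass
class TargetDataset:
    signals: PromoterSignalSet
    timecourse: TimecourseMatrix
    truth: dict
    rescue_wt: pd.DataFrame
    rescue_post: pd.DataFrame

    def __iter__(self):
        return iter((self.signals, self.timecourse, self.truth))


GENE_SPACING = 50_000
PROMOTER_HALFWIDTH = 2_000
CHROM = "chrT"


def _target_labels(config: TargetsConfig):
    n = config.n_genes
    n_resp = round(config.frac_responsive * n)
    n_ind = round(config.frac_indirect * n)
    n_nonresp = round(config.frac_nonresponsive * n)
    n_early = round(config.fraction_early * n_resp)
    n_nonresc = round(config.fraction_nonrescued * n_resp)
    genes = [f"T_{i:04d}" for i in range(n)]
    cls, timing, rescue = {}, {}, {}
    for i, g in enumerate(genes):
        if i < n_resp:
            cls[g] = "responsive"
            timing[g] = "early" if i < n_early else "late"
            rescue[g] = "non_rescued" if i < n_nonresc else "rescued"
        elif i < n_resp + n_ind:
            cls[g], timing[g], rescue[g] = "indirect", "NA", "NA"
        elif i < n_resp + n_ind + n_nonresp:
            cls[g], timing[g], rescue[g] = "nonresponsive", "NA", "NA"
        else:
            cls[g], timing[g], rescue[g] = "null", "NA", "NA"
    return genes, cls, timing, rescue


def _promoter_tracks(genes, cls, timing, config):
    """Piecewise-constant coverage: background 1.0, planted promoter folds."""
    starts, ends, values = [], [], []
    pos = 0
    genome_end = GENE_SPACING * (len(genes) + 1)
    tss = {}
    for i, g in enumerate(genes):
        tss[g] = GENE_SPACING // 2 + i * GENE_SPACING
    marked = {}
    for g in genes:
        if cls[g] in ("responsive", "nonresponsive"):
            fold = (config.promoter_enrichment_low
                    if timing[g] == "early" else config.promoter_enrichment_high)
        else:
            fold = 1.0
        marked[g] = fold
    for g in genes:
        lo = tss[g] - PROMOTER_HALFWIDTH
        hi = tss[g] + PROMOTER_HALFWIDTH
        if pos < lo:
            starts.append(pos); ends.append(lo); values.append(1.0)
        starts.append(lo); ends.append(hi); values.append(marked[g])
        pos = hi
    if pos < genome_end:
        starts.append(pos); ends.append(genome_end); values.append(1.0)
    chroms = [CHROM] * len(starts)
    wt = CoverageTrack.from_arrays(chroms, starts, ends, values)
    ko = CoverageTrack.from_arrays([CHROM], [0], [genome_end], [1.0])
    annotation = pd.DataFrame(
        {"chrom": CHROM,
         "tss": [tss[g] + 1 for g in genes],  # 1-based convention
         "strand": ["+" if i % 2 == 0 else "-" for i in range(len(genes))]},
        index=pd.Index(genes, name="gene_id"))
    annotation["tss0"] = annotation["tss"] - 1
    return wt, ko, annotation


def generate_target_dataset(config: TargetsConfig) -> TargetDataset:
    """Promoter signal, time-course expression and rescue matrices.

    Responsive genes are up-regulated (by ``fold_change_up`` log2 units) from
    the first post-zero timepoint if early, or only at the final timepoint if
    late; indirect genes go up at the final timepoint without promoter mark;
    nonresponsive genes carry the mark but stay flat.  In the rescue
    condition only non-rescued responsive genes remain up versus wild type.
    """
    rng = np.random.default_rng(config.seed)
    genes, cls, timing, rescue = _target_labels(config)
    wt_track, ko_track, annotation = _promoter_tracks(genes, cls, timing, config)
    signals = PromoterSignalSet(
        tracks={"wt": wt_track, "ko": ko_track},
        scaling={"wt": 1.0, "ko": 1.0},
        annotation=annotation)

    n = len(genes)
    k = config.k_replicates
    baseline = EXPR_BASELINE + rng.normal(0.0, 0.5, n)
    tps = [float(t) for t in config.timepoints]
    early_onset, final = tps[1], tps[-1]
    cols = {}
    for t in tps:
        effect = np.zeros(n)
        for i, g in enumerate(genes):
            if cls[g] == "responsive":
                onset = early_onset if timing[g] == "early" else final
                if t >= onset:
                    effect[i] = config.fold_change_up
            elif cls[g] == "indirect" and t >= final:
                effect[i] = config.fold_change_up
        for r in range(1, k + 1):
            cols[f"t{t:g}_r{r}"] = (baseline + effect
                                    + rng.normal(0.0, config.noise_sd, n))
    tc = TimecourseMatrix(pd.DataFrame(cols, index=genes))

    resc_base = EXPR_BASELINE + rng.normal(0.0, 0.5, n)
    resc_effect = np.array(
        [config.fold_change_up if rescue[g] == "non_rescued" else 0.0
         for g in genes])
    rescue_wt = pd.DataFrame(
        {f"r{r}": resc_base + rng.normal(0.0, config.noise_sd, n)
         for r in range(1, k + 1)}, index=genes)
    rescue_post = pd.DataFrame(
        {f"r{r}": resc_base + resc_effect + rng.normal(0.0, config.noise_sd, n)
         for r in range(1, k + 1)}, index=genes)

    truth = {
        "class": cls,
        "timing": timing,
        "rescue": rescue,
        "counts": {c: sum(v == c for v in cls.values())
                   for c in ("responsive", "indirect", "nonresponsive", "null")},
        "config": {k_: (list(v) if isinstance(v, tuple) else v)
                   for k_, v in vars(config).items()
                   if not isinstance(v, MarkKineticsParams)},
    }
    return TargetDataset(signals=signals, timecourse=tc, truth=truth,
                         rescue_wt=rescue_wt, rescue_post=rescue_post)


# ---------------------------------------------------------------------------
# single-cell dataset
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneClassSpec:
    name: str
    n_genes: int
    p_wt: float
    p_ko: float
    deterministic: bool = False

    def __post_init__(self):
        _check_prob("p_wt", self.p_wt)
        _check_prob("p_ko", self.p_ko)
        if self.n_genes <= 0:
            raise ValueError("n_genes must be > 0")


DEFAULT_GENE_CLASSES = (
    GeneClassSpec("responsive", n_genes=8, p_wt=0.1, p_ko=1.0, deterministic=True),
    GeneClassSpec("nonresponsive_sparse", n_genes=8, p_wt=0.05, p_ko=0.4,
                  deterministic=False),
    GeneClassSpec("nonresponsive_stable", n_genes=4, p_wt=0.9, p_ko=0.9,
                  deterministic=False),
)


@dataclass(frozen=True)
class SingleCellConfig:
    n_wt_cells: int = 49
    n_ko_cells: int = 37
    gene_classes: tuple = DEFAULT_GENE_CLASSES
    dye_mislabel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_wt_cells <= 0 or self.n_ko_cells <= 0:
            raise ValueError("cell counts must be positive")
        _check_prob("dye_mislabel_rate", self.dye_mislabel_rate)


@dataclass
class SingleCellDataset:
    expression: pd.DataFrame   # genes x cells, log2 (0 = undetected)
    cell_meta: pd.DataFrame    # dye, set_domain_detected per cell
    truth: dict

    def __iter__(self):
        return iter((self.expression, self.cell_meta, self.truth))


ENZYME_GENE = "Ezh2"


def generate_singlecell_dataset(config: SingleCellConfig) -> SingleCellDataset:
    """Simulate the dye-labelled, genotype-assayed single-cell matrix.

    Deterministic classes switch on all-or-none per cell; stochastic classes
    draw each gene independently.  The enzyme transcript (and the set-domain
    genotype assay) is present only in true wild-type cells; dye labels are
    flipped with ``dye_mislabel_rate``.
    """
    rng = np.random.default_rng(config.seed)
    n_cells = config.n_wt_cells + config.n_ko_cells
    cells = [f"C{i:04d}" for i in range(n_cells)]
    genotype = np.array(["wt"] * config.n_wt_cells + ["ko"] * config.n_ko_cells)

    gene_rows = {}
    class_of = {}
    for spec in config.gene_classes:
        p = np.where(genotype == "wt", spec.p_wt, spec.p_ko)
        if spec.deterministic:
            on_cell = rng.random(n_cells) < p
            detected = np.tile(on_cell, (spec.n_genes, 1))
        else:
            detected = rng.random((spec.n_genes, n_cells)) < p
        for j in range(spec.n_genes):
            gene = f"{spec.name}_{j:02d}"
            values = np.where(
                detected[j],
                np.maximum(rng.normal(5.0, 1.0, n_cells), 0.5), 0.0)
            gene_rows[gene] = values
            class_of[gene] = spec.name
    enzyme = np.where(genotype == "wt",
                      np.maximum(rng.normal(5.0, 1.0, n_cells), 0.5), 0.0)
    gene_rows[ENZYME_GENE] = enzyme
    class_of[ENZYME_GENE] = "enzyme"

    expr = pd.DataFrame(gene_rows, index=cells).T
    set_domain = genotype == "wt"
    correct_dye = np.where(genotype == "wt", "DiI", "DiO")
    flipped = rng.random(n_cells) < config.dye_mislabel_rate
    dye = np.where(flipped,
                   np.where(correct_dye == "DiI", "DiO", "DiI"), correct_dye)
    cell_meta = pd.DataFrame(
        {"dye": dye, "set_domain_detected": set_domain},
        index=pd.Index(cells, name="cell_id"))
    truth = {
        "genotype": dict(zip(cells, genotype)),
        "flipped": [c for c, f in zip(cells, flipped) if f],
        "class_of_gene": class_of,
        "config": {
            "n_wt_cells": config.n_wt_cells,
            "n_ko_cells": config.n_ko_cells,
            "dye_mislabel_rate": config.dye_mislabel_rate,
            "seed": config.seed,
            "gene_classes": [vars(s) for s in config.gene_classes],
        },
    }
    return SingleCellDataset(expression=expr, cell_meta=cell_meta, truth=truth)
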