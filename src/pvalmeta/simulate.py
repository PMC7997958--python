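"""Synthetic-data generators and simulation experiment drivers.

Two study designs are emulated:

* **t-test simulation** — associated p-values (p1) come from one-sample
  one-tailed t-tests of N(mean, 1) samples with the mean drawn from
  [0.03, 0.1] and the sample size from [30, 2000]; unassociated
  p-values (p0) are uniform on a configurable sub-interval of [0, 1].
  Drivers measure type-I error (all-null vectors at cutoff 0.05) and
  power (cutoff 0.01) as increasing numbers of p0-values are appended
  to a fixed set of p1-values — the incomplete-association stress test.

* **RNA-seq meta-analysis simulation** — per study, a genes x samples
  negative-binomial count matrix with log-normal gene means and a
  decreasing mean-dispersion trend; in associated studies a fixed
  fraction of genes is differentially expressed with fold change >=
  1.3 (direction random per gene, consistent across associated
  studies).  Per-study differential expression is tested by Welch's t
  on log2 CPM, and the per-gene p-values/signs are fed through the
  directional combiners; AUC / TPR / realized FDR are computed against
  the simulated truth.

All randomness flows through a single seeded numpy Generator recorded
in the configs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from . import effectmeta, ordstat, pcombine
from .evaluate import auc_score, bh_qvalues, tpr_truefdr
from .types import EffectEvidence, InvalidInputError, StudyEvidence

__all__ = [
    "TTestSimConfig",
    "RnaSeqSimConfig",
    "SimTruth",
    "TTestDraw",
    "simulate_ttest_pvalues",
    "run_type1_experiment",
    "run_power_experiment",
    "run_prediction_experiment",
    "simulate_rnaseq_meta",
    "per_study_de_test",
    "run_rnaseq_meta_experiment",
    "write_experiment",
]

#: Combiners exercised by the t-test benchmarks.
DEFAULT_PCOMBINE_METHODS = ("wfisher", "ordmeta", "stouffer", "wz", "lancaster", "fisher")


@dataclass
class SimTruth:
    """Ground-truth association indicators for a simulated scenario."""

    feature_assoc: np.ndarray
    study_assoc: Optional[np.ndarray] = None
    direction: Optional[np.ndarray] = None


@dataclass
class TTestSimConfig:
    """Scenario description for the t-test simulation.

    ``sample_size_range`` is sampled uniformly (integer sizes), as is
    ``mean_range``; one (size, mean) pair is drawn per associated study
    per replicate.
    """

    n_assoc: int = 4
    n_unassoc_max: int = 30
    sample_size_range: tuple[float, float] = (30.0, 2000.0)
    mean_range: tuple[float, float] = (0.03, 0.1)
    p0_interval: tuple[float, float] = (0.0, 1.0)
    reps: int = 1000
    reps_type1: int = 100_000
    alpha_power: float = 0.01
    alpha_type1: float = 0.05
    #: draw one (size, mean) pair per replicate shared by all associated
    #: studies instead of one pair per study
    shared_effect_pairs: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.p0_interval
        if not (0.0 <= lo < hi <= 1.0):
            raise InvalidInputError("p0_interval must be a sub-interval of [0, 1]")
        if self.sample_size_range[0] < 2 or self.sample_size_range[0] > self.sample_size_range[1]:
            raise InvalidInputError("degenerate sample size range")
        if self.mean_range[0] > self.mean_range[1]:
            raise InvalidInputError("degenerate mean range")
        if self.reps < 1 or self.n_assoc < 0 or self.n_unassoc_max < 0:
            raise InvalidInputError("counts must be non-negative, reps >= 1")


@dataclass
class TTestDraw:
    """One replicate of the t-test generator."""

    p_assoc: np.ndarray
    size_assoc: np.ndarray
    p_unassoc: np.ndarray
    size_unassoc: np.ndarray
    truth: SimTruth

    @property
    def p(self) -> np.ndarray:
        return np.concatenate([self.p_assoc, self.p_unassoc])

    @property
    def sizes(self) -> np.ndarray:
        return np.concatenate([self.size_assoc, self.size_unassoc])


def _draw_sizes(rng: np.random.Generator, lo: float, hi: float, k: int) -> np.ndarray:
    if k == 0:
        return np.empty(0)
    return np.floor(rng.uniform(lo, hi + 1.0, size=k)).clip(lo, hi)


def _one_sample_t_pvalues(rng: np.random.Generator, means, sizes) -> np.ndarray:
    """One-tailed (upper) one-sample t-test p-values of N(mean, 1) samples."""
    out = np.empty(len(means))
    for i, (mu, m) in enumerate(zip(means, sizes)):
        m = int(m)
        x = rng.normal(mu, 1.0, size=m)
        tstat = x.mean() / (x.std(ddof=1) / np.sqrt(m))
        out[i] = stats.t.sf(tstat, m - 1)
    return out


def simulate_ttest_pvalues(
    cfg: TTestSimConfig, rng: Optional[np.random.Generator] = None
) -> TTestDraw:
    """Draw one replicate: associated t-test p-values plus uniform nulls."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    if cfg.shared_effect_pairs and cfg.n_assoc > 0:
        s1 = np.repeat(_draw_sizes(rng, *cfg.sample_size_range, 1), cfg.n_assoc)
        means = np.repeat(rng.uniform(*cfg.mean_range, size=1), cfg.n_assoc)
    else:
        s1 = _draw_sizes(rng, *cfg.sample_size_range, cfg.n_assoc)
        means = rng.uniform(*cfg.mean_range, size=cfg.n_assoc)
    p1 = _one_sample_t_pvalues(rng, means, s1)
    p0 = rng.uniform(*cfg.p0_interval, size=cfg.n_unassoc_max)
    s0 = _draw_sizes(rng, *cfg.sample_size_range, cfg.n_unassoc_max)
    truth = SimTruth(
        feature_assoc=np.r_[np.ones(cfg.n_assoc, bool), np.zeros(cfg.n_unassoc_max, bool)]
    )
    return TTestDraw(p1, s1, p0, s0, truth)


def _batch_pvalues(method: str, P: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Dispatch one method's vectorised combined p-values (rows = replicates)."""
    if method == "fisher":
        return pcombine.fisher_pvalues_batch(P)
    if method == "stouffer":
        return pcombine.stouffer_pvalues_batch(P)
    if method == "wz":
        return pcombine.weighted_z_pvalues_batch(P, sizes)
    if method == "lancaster":
        return pcombine.lancaster_pvalues_batch(P, sizes)
    if method == "wfisher":
        return pcombine.wfisher_pvalues_batch(P, sizes)
    if method == "ordmeta":
        return ordstat.ordmeta_pvalues_batch(P, exact_small=False)
    raise InvalidInputError(f"no vectorised path for method {method!r}")


def run_type1_experiment(
    cfg: TTestSimConfig,
    methods: Sequence[str] = DEFAULT_PCOMBINE_METHODS,
    n_pvalues: Sequence[int] = (2, 10, 30, 100),
    reps: Optional[int] = None,
    equal_sample_size: float = 100.0,
) -> pd.DataFrame:
    """Empirical type-I rate of each combiner on all-null p-value vectors.

    Null p-values are Uniform(0, 1) — exactly the one-tailed zero-effect
    t-test distribution.  Weighted methods receive equal sample sizes.
    Returns a tidy frame (method, n_pvalues, reps, type1_rate).
    """
    reps = cfg.reps_type1 if reps is None else reps
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for m in n_pvalues:
        P = rng.uniform(size=(reps, m))
        sizes = np.full(m, equal_sample_size)
        for method in methods:
            pc = _batch_pvalues(method, P, sizes)
            rate = float((pc < cfg.alpha_type1).mean())
            rows.append({"method": method, "n_pvalues": m, "reps": reps,
                         "type1_rate": rate})
    return pd.DataFrame(rows)


def run_power_experiment(
    cfg: TTestSimConfig,
    methods: Sequence[str] = DEFAULT_PCOMBINE_METHODS,
    n_unassoc_grid: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Power of each combiner as null p-values are appended.

    Per replicate, one set of associated p-values is drawn and reused
    across the whole p0-count trace (matched draws keep the power curves
    comparable along the x-axis).  Power is the fraction of replicates
    with combined p below ``cfg.alpha_power``.  Returns a tidy frame
    (method, n_assoc, n_unassoc, power).
    """
    rng = np.random.default_rng(cfg.seed)
    grid = list(range(cfg.n_unassoc_max + 1)) if n_unassoc_grid is None else list(n_unassoc_grid)
    reps = cfg.reps
    P1 = np.empty((reps, cfg.n_assoc))
    S1 = np.empty((reps, cfg.n_assoc))
    P0 = np.empty((reps, cfg.n_unassoc_max))
    S0 = np.empty((reps, cfg.n_unassoc_max))
    for i in range(reps):
        draw = simulate_ttest_pvalues(cfg, rng)
        P1[i], S1[i] = draw.p_assoc, draw.size_assoc
        P0[i], S0[i] = draw.p_unassoc, draw.size_unassoc
    rows = []
    for n0 in grid:
        P = np.hstack([P1, P0[:, :n0]])
        sizes = np.hstack([S1, S0[:, :n0]])
        P = np.clip(P, 1e-320, 1.0 - 1e-16)
        for method in methods:
            pc = _batch_pvalues(method, P, sizes)
            rows.append({
                "method": method,
                "n_assoc": cfg.n_assoc,
                "n_unassoc": n0,
                "power": float((pc < cfg.alpha_power).mean()),
            })
    return pd.DataFrame(rows)


def run_prediction_experiment(
    n_inputs: Sequence[int] = (10, 30, 100),
    reps: int = 100,
    cfg: Optional[TTestSimConfig] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Sensitivity/specificity of the associated-study prediction.

    Half of the inputs are associated t-test p-values, half uniform
    nulls; the studies flagged by the minimum-marginal optimal order are
    scored against the truth.  Returns one row per (n_inputs, rep).
    """
    base = cfg or TTestSimConfig()
    rng = np.random.default_rng(seed)
    rows = []
    for n in n_inputs:
        half = n // 2
        scen = TTestSimConfig(
            n_assoc=half,
            n_unassoc_max=n - half,
            sample_size_range=base.sample_size_range,
            mean_range=base.mean_range,
            p0_interval=(0.0, 1.0),
            reps=reps,
            seed=base.seed,
        )
        for rep in range(reps):
            draw = simulate_ttest_pvalues(scen, rng)
            mask = ordstat.predict_associated(StudyEvidence(p=draw.p))
            truth = draw.truth.feature_assoc
            tp = (mask & truth).sum()
            tn = (~mask & ~truth).sum()
            rows.append({
                "n_inputs": n,
                "rep": rep,
                "sensitivity": tp / truth.sum(),
                "specificity": tn / (~truth).sum(),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# RNA-seq meta-analysis simulation
# ---------------------------------------------------------------------------

@dataclass
class RnaSeqSimConfig:
    """Scenario description for the multi-study RNA-seq count simulation.

    Gene base means are log-normal (``mean_log_mu``, ``mean_log_sigma``
    on the natural-log scale, defaults giving a median of ~55 counts);
    per-gene dispersions follow the decreasing trend
    ``(disp_base + disp_slope / mu) * Gamma(disp_shape, 1/disp_shape)``.
    Fold changes are ``min_fold_change + Exponential(fc_scale)`` with a
    random but study-consistent direction per DE gene.
    """

    n_genes: int = 1000
    n_studies: int = 20
    n_assoc_studies: int = 2
    de_fraction: float = 0.10
    min_fold_change: float = 1.3
    samples_per_group: int = 20
    mean_log_mu: float = 4.0
    mean_log_sigma: float = 1.3
    disp_base: float = 0.05
    disp_slope: float = 2.0
    disp_shape: float = 5.0
    fc_scale: float = 0.5
    reps: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.n_assoc_studies <= self.n_studies):
            raise InvalidInputError("n_assoc_studies must lie in 1..n_studies")
        if not (0.0 < self.de_fraction < 1.0):
            raise InvalidInputError("de_fraction must lie in (0, 1)")
        if self.min_fold_change <= 1.0:
            raise InvalidInputError("min_fold_change must exceed 1")
        if self.samples_per_group < 2:
            raise InvalidInputError("need at least 2 samples per group")


def simulate_rnaseq_meta(
    cfg: RnaSeqSimConfig, rng: Optional[np.random.Generator] = None
) -> tuple[list[np.ndarray], list[np.ndarray], SimTruth]:
    """Simulate per-study negative-binomial count matrices.

    Returns (count matrices genes x samples, group-label vectors, truth).
    The first ``n_assoc_studies`` studies carry the differential
    expression; the DE gene set and per-gene direction are shared across
    associated studies.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    G, n_de = cfg.n_genes, int(round(cfg.de_fraction * cfg.n_genes))
    base_mu = rng.lognormal(cfg.mean_log_mu, cfg.mean_log_sigma, size=G)
    de_genes = rng.choice(G, size=n_de, replace=False)
    de_mask = np.zeros(G, bool)
    de_mask[de_genes] = True
    direction = np.where(rng.random(G) < 0.5, 1, -1)
    fold = cfg.min_fold_change + rng.exponential(cfg.fc_scale, size=G)
    study_assoc = np.r_[np.ones(cfg.n_assoc_studies, bool),
                        np.zeros(cfg.n_studies - cfg.n_assoc_studies, bool)]
    counts_list, group_list = [], []
    spg = cfg.samples_per_group
    groups = np.r_[np.zeros(spg, int), np.ones(spg, int)]
    for s in range(cfg.n_studies):
        scale = rng.uniform(0.7, 1.3)
        mu1 = base_mu * scale
        mu2 = mu1.copy()
        if study_assoc[s]:
            fc = np.where(direction > 0, fold, 1.0 / fold)
            mu2[de_mask] = mu1[de_mask] * fc[de_mask]
        phi = (cfg.disp_base + cfg.disp_slope / mu1) * rng.gamma(
            cfg.disp_shape, 1.0 / cfg.disp_shape, size=G
        )
        nb_n = 1.0 / phi
        counts = np.empty((G, 2 * spg), dtype=np.int64)
        counts[:, :spg] = rng.negative_binomial(
            nb_n[:, None], (nb_n / (nb_n + mu1))[:, None], size=(G, spg)
        )
        counts[:, spg:] = rng.negative_binomial(
            nb_n[:, None], (nb_n / (nb_n + mu2))[:, None], size=(G, spg)
        )
        counts_list.append(counts)
        group_list.append(groups.copy())
    truth = SimTruth(feature_assoc=de_mask, study_assoc=study_assoc, direction=direction)
    return counts_list, group_list, truth


@dataclass
class DeTestResult:
    """Per-gene two-tailed p-values, effect signs, and log2-CPM effects."""

    p: np.ndarray
    sign: np.ndarray
    effect: np.ndarray
    se: np.ndarray


def per_study_de_test(counts: np.ndarray, groups: np.ndarray) -> DeTestResult:
    """Welch's t-test per gene on log2(CPM + 0.5) between two groups."""
    counts = np.asarray(counts)
    groups = np.asarray(groups)
    if set(np.unique(groups)) - {0, 1}:
        raise InvalidInputError("groups must be coded 0/1")
    n1, n2 = int((groups == 0).sum()), int((groups == 1).sum())
    if min(n1, n2) < 2:
        raise InvalidInputError("each group needs at least 2 samples")
    lib = counts.sum(axis=0).astype(float)
    cpm = counts / lib[None, :] * 1e6
    y = np.log2(cpm + 0.5)
    y1, y2 = y[:, groups == 0], y[:, groups == 1]
    m1, m2 = y1.mean(axis=1), y2.mean(axis=1)
    v1, v2 = y1.var(axis=1, ddof=1), y2.var(axis=1, ddof=1)
    se = np.sqrt(v1 / n1 + v2 / n2)
    se = np.maximum(se, 1e-12)
    tstat = (m2 - m1) / se
    df = (v1 / n1 + v2 / n2) ** 2 / (
        (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1) + 1e-300
    )
    df = np.maximum(df, 1.0)
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    sign = np.where(tstat >= 0, 1, -1)
    return DeTestResult(p=np.clip(p, 1e-320, 1.0), sign=sign, effect=m2 - m1, se=se)


def _directional_batch(method: str, P: np.ndarray, SGN: np.ndarray,
                       sizes: np.ndarray) -> np.ndarray:
    """Two-tailed directional combination, vectorised over features (rows)."""
    U = np.where(SGN > 0, P / 2.0, 1.0 - P / 2.0)
    U = np.clip(U, 1e-320, 1.0 - 1e-16)
    pu = _batch_pvalues(method, U, sizes)
    pd_ = _batch_pvalues(method, np.clip(1.0 - U, 1e-320, 1.0 - 1e-16), sizes)
    return np.minimum(1.0, 2.0 * np.minimum(pu, pd_))


def _rop_directional(P: np.ndarray, SGN: np.ndarray, r: int) -> np.ndarray:
    n = P.shape[1]
    rr = np.arange(1, n + 1, dtype=float)
    out = []
    for U in (np.where(SGN > 0, P / 2.0, 1.0 - P / 2.0),):
        for V in (U, 1.0 - U):
            Vs = np.sort(np.clip(V, 1e-320, 1.0 - 1e-16), axis=1)
            out.append(special.betainc(r, n - r + 1, Vs[:, r - 1]))
    return np.minimum(1.0, 2.0 * np.minimum(out[0], out[1]))


def run_rnaseq_meta_experiment(
    cfg: RnaSeqSimConfig,
    methods: Sequence[str] = ("wfisher", "ordmeta", "fisher", "stouffer", "wz", "fem", "rem"),
    q_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Full pipeline: simulate counts, per-study DE tests, combine, score.

    Methods may be combiner tags (applied through the directional
    wrapper with per-study sample sizes as weights), ``fem``/``rem``
    (effect-size pooling of the per-study log2-CPM effects), or
    ``rop_<r>`` for a fixed-order marginal.  Returns one row per
    (method, rep) with AUC, TPR, realized FDR, and significant count.
    """
    rng = np.random.default_rng(cfg.seed)
    rows = []
    sizes = np.full(cfg.n_studies, 2.0 * cfg.samples_per_group)
    for rep in range(cfg.reps):
        counts_list, group_list, truth = simulate_rnaseq_meta(cfg, rng)
        tests = [per_study_de_test(c, g) for c, g in zip(counts_list, group_list)]
        P = np.column_stack([t.p for t in tests])
        SGN = np.column_stack([t.sign for t in tests])
        BETA = np.column_stack([t.effect for t in tests])
        SE = np.column_stack([t.se for t in tests])
        for method in methods:
            if method in ("fem", "rem"):
                pool = (effectmeta.fixed_effect_meta if method == "fem"
                        else effectmeta.random_effect_meta)
                pc = np.array([
                    pool(EffectEvidence(beta=BETA[g], se=SE[g])).p_value
                    for g in range(cfg.n_genes)
                ])
            elif method.startswith("rop"):
                r = int(method.split("_", 1)[1]) if "_" in method else 2
                pc = _rop_directional(P, SGN, r)
            else:
                pc = _directional_batch(method, P, SGN, sizes)
            q = bh_qvalues(pc)
            metrics = tpr_truefdr(q, truth.feature_assoc, cutoff=q_cutoff)
            auc = auc_score(-pc, truth.feature_assoc)
            rows.append({
                "method": method,
                "rep": rep,
                "n_assoc_studies": cfg.n_assoc_studies,
                "de_fraction": cfg.de_fraction,
                "auc": auc,
                "tpr": metrics.tpr,
                "true_fdr": metrics.true_fdr,
                "n_significant": metrics.n_significant,
            })
    return pd.DataFrame(rows)


def write_experiment(df: pd.DataFrame, path: "str | Path", cfg=None) -> None:
    """Write a tidy result table plus a key-value run-metadata sidecar."""
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    if cfg is not None:
        meta = path.with_suffix(path.suffix + ".meta.txt")
        with open(meta, "w") as fh:
            fh.write(f"config_class\t{type(cfg).__name__}\n")
            for key, val in asdict(cfg).items():
                fh.write(f"{key}\t{val}\n")
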