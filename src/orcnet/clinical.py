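"""Module scores and clinical association statistics.

Per-patient module scores are the mean, over a module's genes, of the
on-minus-pre expression difference scaled by each gene's across-patient
standard deviation (no mean centering, so the sign of the change is kept).
Scores are then related to outcome by multivariable Cox regression,
Kaplan-Meier median split with log-rank test, Kruskal-Wallis across RECIST
response groups, per-gene rank-sum tests with Benjamini-Hochberg
correction, and hypergeometric over-representation against GMT gene sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .clustering import ModulePartition

__all__ = [
    "scale_delta",
    "module_scores",
    "prepare_clinical",
    "cox_multivariable",
    "km_logrank_median_split",
    "kruskal_wallis_response",
    "per_gene_response_test",
    "bh_adjust",
    "ora_hypergeometric",
    "read_gmt",
]

RESPONSE_GROUPS = ("CR/PR", "SD", "PD")


def scale_delta(delta: pd.DataFrame) -> pd.DataFrame:
    """Divide each gene row by its across-patient SD (ddof=1), keeping signs.

    Unlike a z-score the mean is not subtracted, so positive and negative
    expression changes stay positive and negative.  Zero-variance rows pass
    through unscaled with a warning.
    """
    if delta.shape[1] < 2:
        raise ValueError("need at least 2 patients to scale")
    sd = delta.std(axis=1, ddof=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} zero-variance gene(s) left unscaled",
                      stacklevel=2)
    return delta.div(sd.where(~flat, 1.0), axis=0)


def module_scores(scaled: pd.DataFrame, partition: ModulePartition) -> pd.DataFrame:
    """Patient x module table of mean scaled expression difference."""
    missing = [g for g in scaled.index if g not in partition.labels]
    if missing:
        raise ValueError(f"genes without module labels: {missing[:5]}")
    labels = pd.Series({g: partition.labels[g] for g in scaled.index})
    counts = labels.value_counts()
    for m in range(1, partition.n_modules + 1):
        if counts.get(m, 0) == 0:
            raise ValueError(f"module {m} has no genes in the scaled matrix")
    scores = scaled.groupby(labels).mean().T
    scores.columns = [f"module_{m}" for m in scores.columns]
    return scores


def prepare_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Recode RECIST categories: drop NE, merge CR and PR into 'CR/PR'."""
    out = clinical.copy()
    if "patient_id" in out.columns:
        out = out.set_index("patient_id", drop=False)
    out["response_group"] = out["response"].map(
        {"CR": "CR/PR", "PR": "CR/PR", "SD": "SD", "PD": "PD"}
    )
    return out[out["response"] != "NE"]


def cox_multivariable(scores: pd.DataFrame, clinical: pd.DataFrame) -> pd.DataFrame:
    """Multivariable Cox PH fit of survival on all module scores jointly.

    Returns one row per module: coefficient, hazard ratio, 95% CI, Wald p.
    Zero-variance or collinear covariates are rejected by name; fewer than
    10 events triggers a warning.
    """
    df = scores.join(clinical[["os_time", "os_event"]], how="inner").dropna()
    covs = list(scores.columns)
    for c in covs:
        if df[c].nunique() <= 1:
            raise ValueError(f"covariate {c} has zero variance")
    X = df[covs].to_numpy()
    if np.linalg.matrix_rank(X - X.mean(0)) < len(covs):
        corr = df[covs].corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.stack().idxmax()
        raise ValueError(f"collinear covariates (e.g. {worst[0]} vs {worst[1]})")
    if df["os_event"].sum() < 10:
        warnings.warn("fewer than 10 events; Cox estimates may be unstable",
                      stacklevel=2)
    cph = CoxPHFitter()
    cph.fit(df[covs + ["os_time", "os_event"]],
            duration_col="os_time", event_col="os_event")
    s = cph.summary
    return pd.DataFrame(
        {
            "module": s.index,
            "coef": s["coef"],
            "hr": s["exp(coef)"],
            "ci_low": s["exp(coef) lower 95%"],
            "ci_high": s["exp(coef) upper 95%"],
            "p": s["p"],
        }
    ).reset_index(drop=True)


@dataclass
class MedianSplitResult:
    """Two-group Kaplan-Meier comparison after a median split on one score."""

    statistic: float
    p_value: float
    median: float
    n_low: int
    n_high: int
    curves: dict[str, pd.DataFrame]


def km_logrank_median_split(score: pd.Series, clinical: pd.DataFrame) -> MedianSplitResult:
    """Split patients at the median score (ties to low) and compare survival.

    Fits product-limit curves per group and runs the two-group log-rank test.
    """
    df = clinical.loc[clinical.index.intersection(score.index),
                      ["os_time", "os_event"]].copy()
    s = score.loc[df.index]
    if s.nunique() <= 1:
        raise ValueError("all scores equal; median split impossible")
    med = float(s.median())
    low = s <= med
    if low.sum() < 2 or (~low).sum() < 2:
        raise ValueError("median split leaves a group with fewer than 2 patients")
    curves = {}
    for name, mask in [("low", low), ("high", ~low)]:
        kmf = KaplanMeierFitter()
        kmf.fit(df.loc[mask, "os_time"], df.loc[mask, "os_event"], label=name)
        curves[name] = kmf.survival_function_
    res = logrank_test(
        df.loc[low, "os_time"], df.loc[~low, "os_time"],
        df.loc[low, "os_event"], df.loc[~low, "os_event"],
    )
    return MedianSplitResult(
        statistic=float(res.test_statistic), p_value=float(res.p_value),
        median=med, n_low=int(low.sum()), n_high=int((~low).sum()), curves=curves,
    )


def kruskal_wallis_response(score: pd.Series, clinical: pd.DataFrame):
    """Kruskal-Wallis H (tie-corrected) of a module score across response groups.

    Groups are CR/PR, SD, PD after NE removal; returns (H, p, group means).
    """
    df = prepare_clinical(clinical) if "response_group" not in clinical else clinical
    df = df.loc[df.index.intersection(score.index)]
    groups = {
        g: score.loc[df.index[df["response_group"] == g]].to_numpy()
        for g in RESPONSE_GROUPS
    }
    nonempty = [v for v in groups.values() if len(v) > 0]
    if len(nonempty) < 2:
        raise ValueError("need at least 2 nonempty response groups")
    h, p = stats.kruskal(*nonempty)
    means = {g: (float(np.mean(v)) if len(v) else float("nan"))
             for g, v in groups.items()}
    return float(h), float(p), means


def per_gene_response_test(
    scaled: pd.DataFrame, clinical: pd.DataFrame, include_sd: bool = False
) -> pd.DataFrame:
    """Per-gene two-sample Wilcoxon rank-sum of CR/PR vs PD expression change.

    SD patients are excluded from the contrast (their group mean is still
    reported when ``include_sd``).  P-values are Benjamini-Hochberg adjusted
    across the genes tested; group means of the scaled change are reported.
    """
    df = prepare_clinical(clinical) if "response_group" not in clinical else clinical
    patients = scaled.columns.intersection(df.index)
    df = df.loc[patients]
    crpr = df.index[df["response_group"] == "CR/PR"]
    pd_grp = df.index[df["response_group"] == "PD"]
    if len(crpr) == 0 or len(pd_grp) == 0:
        raise ValueError("both CR/PR and PD groups must be nonempty")
    degenerate = len(crpr) < 2 or len(pd_grp) < 2
    if degenerate:
        warnings.warn("a response group has fewer than 2 patients; p undefined",
                      stacklevel=2)
    rows = []
    for gene in scaled.index:
        x = scaled.loc[gene, crpr].to_numpy()
        y = scaled.loc[gene, pd_grp].to_numpy()
        if degenerate:
            stat, p = float("nan"), float("nan")
        else:
            stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
        row = {
            "gene": gene,
            "mean_crpr": float(np.mean(x)),
            "mean_pd": float(np.mean(y)),
            "statistic": float(stat),
            "p": float(p),
        }
        if include_sd:
            sd_grp = df.index[df["response_group"] == "SD"]
            row["mean_sd"] = float(scaled.loc[gene, sd_grp].mean()) if len(sd_grp) else float("nan")
        rows.append(row)
    out = pd.DataFrame(rows)
    valid = out["p"].notna()
    out["fdr"] = np.nan
    if valid.any():
        out.loc[valid, "fdr"] = bh_adjust(out.loc[valid, "p"].to_numpy())
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: name, description, then member genes, tab-separated."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def ora_hypergeometric(
    module_genes: set[str], gene_sets: dict[str, list[str]], universe: set[str]
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of each gene set.

    For a universe of N genes, a set of K (after intersecting with the
    universe) and a module of n, the p-value of observing overlap k is
    P[X >= k] with X ~ Hypergeom(N, K, n).  BH adjustment runs across sets;
    sets with FDR < 0.05 are flagged significant.
    """
    if not universe:
        raise ValueError("empty gene universe")
    if not module_genes <= universe:
        raise ValueError("module genes must be contained in the universe")
    N, n = len(universe), len(module_genes)
    rows = []
    for name, members in gene_sets.items():
        in_universe = set(members) & universe
        overlap = sorted(in_universe & module_genes)
        K, k = len(in_universe), len(overlap)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({"set": name, "overlap": k, "module_size": n, "set_size": K,
                     "p": min(p, 1.0), "overlap_genes": ",".join(overlap)})
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = bh_adjust(out["p"].to_numpy())
        out["significant"] = out["fdr"] < 0.05
        out = out.sort_values("p", kind="stable").reset_index(drop=True)
    return out
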