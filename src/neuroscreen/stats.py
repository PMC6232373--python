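"""Nonparametric screening statistics and derived per-image variables.

The screening data (per-image counts, lengths, alignment percentages,
grouped by substrate) are skewed and bounded, so the layer is fully
nonparametric: a Lilliefors normality check per group (Kolmogorov-Smirnov
against a normal with estimated mean and sd, p by Monte-Carlo null),
the Kruskal-Wallis omnibus test with Dunn's post hoc pairwise test, the
Spearman rank correlation between variables, and median/IQR summaries.

Derived per-image variables: the differentiated fraction (cells with at
least one neurite over all cells), the bipolar/unipolar and
multipolar/unipolar ratios (missing when no unipolar cells), branching
fractions per polarity class, mean neurite length, and the three
alignment percentages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .detection import ScreeningRecord
from .errors import DegenerateInputError

__all__ = [
    "GroupedVariable",
    "StatsReport",
    "lilliefors",
    "kruskal_wallis",
    "dunns_posthoc",
    "spearman",
    "summarize_median_iqr",
    "derive_screening_variables",
    "run_stats",
]

_LILLIEFORS_SEED = 20260919  # fixed internal seed: reproducible Monte-Carlo null


@dataclass
class GroupedVariable:
    """One screening variable, split into per-substrate groups."""

    name: str
    groups: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        clean = {}
        for key, vals in self.groups.items():
            arr = np.asarray(vals, dtype=float)
            if arr.size == 0:
                raise ValueError(f"group {key!r} of {self.name!r} is empty")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"group {key!r} of {self.name!r} holds non-finite values")
            clean[key] = arr
        self.groups = clean


@dataclass
class StatsReport:
    """Per-variable test battery: normality, omnibus, post hoc, summaries."""

    variable: str
    lilliefors_p: dict[str, float]
    kruskal_h: float
    kruskal_p: float
    dunn: pd.DataFrame
    median_iqr: dict[str, tuple[float, float, float]]
    alpha: float = 0.05

    def to_text(self) -> str:
        lines = [f"== {self.variable} =="]
        for g, (med, q1, q3) in self.median_iqr.items():
            lil = self.lilliefors_p.get(g, float("nan"))
            lines.append(f"  {g}: median {med:.3g} (IQR {q1:.3g}-{q3:.3g}), Lilliefors p={lil:.3g}")
        lines.append(f"  Kruskal-Wallis H={self.kruskal_h:.4g}, p={self.kruskal_p:.3g}")
        sig = self.dunn[self.dunn["significant"]]
        if len(sig):
            for _, row in sig.iterrows():
                lines.append(
                    f"  Dunn {row['group1']} vs {row['group2']}: z={row['z']:.3g}, "
                    f"p_adj={row['p_adj']:.3g} *"
                )
        else:
            lines.append(f"  Dunn: no pair significant at alpha={self.alpha}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# tests


def _ks_normal_distance(x: np.ndarray) -> float:
    """KS distance of a sample to a normal with its own estimated mean/sd."""
    n = x.size
    z = np.sort((x - x.mean()) / x.std(ddof=1))
    cdf = sps.norm.cdf(z)
    i = np.arange(1, n + 1)
    return float(np.max(np.maximum(i / n - cdf, cdf - (i - 1) / n)))


def lilliefors(values, n_reps: int = 10000) -> tuple[float, float]:
    """Lilliefors normality test: (D statistic, Monte-Carlo p-value).

    The Kolmogorov-Smirnov correction for estimated parameters: the null
    distribution of D is simulated from standard-normal samples of the
    same size (fixed internal seed), so no critical-value table is needed.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError("lilliefors requires n >= 4")
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant sample has no defined normality statistic")
    d_obs = _ks_normal_distance(x)
    rng = np.random.default_rng(_LILLIEFORS_SEED)
    n = x.size
    sims = rng.standard_normal((n_reps, n))
    sims = np.sort((sims - sims.mean(axis=1, keepdims=True)) / sims.std(axis=1, ddof=1, keepdims=True), axis=1)
    cdf = sps.norm.cdf(sims)
    i = np.arange(1, n + 1)
    d_null = np.max(np.maximum(i / n - cdf, cdf - (i - 1) / n), axis=1)
    p = (1.0 + np.sum(d_null >= d_obs)) / (n_reps + 1.0)
    return d_obs, float(p)


def kruskal_wallis(groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("kruskal_wallis requires at least 2 groups")
    if any(g.size < 1 for g in groups):
        raise ValueError("every group must hold at least one value")
    if sum(g.size for g in groups) < 5:
        raise ValueError("kruskal_wallis requires a total n >= 5")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:  # every observation tied: no evidence either way
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def dunns_posthoc(groups, labels=None, alpha: float = 0.05, adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's post hoc pairwise test after Kruskal-Wallis.

    z for each pair is the difference of mean pooled (tie-corrected)
    ranks over its standard error; two-sided p-values are multiplicity
    adjusted over all pairs (``bonferroni`` default, ``holm`` or ``none``).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("dunns_posthoc requires at least 2 groups")
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    if len(labels) != len(groups):
        raise ValueError("labels/groups length mismatch")
    if adjust not in ("bonferroni", "holm", "none"):
        raise ValueError("adjust must be one of bonferroni, holm, none")

    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    sizes = [g.size for g in groups]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [ranks[bounds[i]:bounds[i + 1]].mean() for i in range(len(groups))]

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))

    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = np.sqrt(
                (n_total * (n_total + 1) / 12.0 - tie_term) * (1.0 / sizes[i] + 1.0 / sizes[j])
            )
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            p_raw = 2.0 * sps.norm.sf(abs(z))
            rows.append({"group1": labels[i], "group2": labels[j], "z": z, "p_raw": p_raw})
    table = pd.DataFrame(rows)
    if adjust == "none":
        table["p_adj"] = table["p_raw"]
    else:
        table["p_adj"] = multipletests(table["p_raw"], method=adjust)[1]
    table["significant"] = table["p_adj"] < alpha
    return table


def spearman(x, y, ci: bool = False, ci_level: float = 0.99):
    """Spearman rank correlation with two-tailed p (t approximation).

    With ``ci=True`` also returns the Fisher-transform confidence
    interval at ``ci_level`` (99% by default, matching the screening
    convention of significance at P < 0.01 for correlations).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 4:
        raise ValueError("spearman requires n >= 4")
    r, p = sps.spearmanr(x, y)
    r, p = float(r), float(p)
    if not ci:
        return r, p
    z = np.arctanh(np.clip(r, -0.999999, 0.999999))
    se = 1.0 / np.sqrt(x.size - 3)
    zc = sps.norm.ppf(0.5 + ci_level / 2.0)
    lo, hi = np.tanh(z - zc * se), np.tanh(z + zc * se)
    return r, p, (float(lo), float(hi))


def summarize_median_iqr(values) -> tuple[float, float, float]:
    """(median, Q1, Q3) with linear quantile interpolation."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    med, q1, q3 = np.percentile(x, [50, 25, 75], method="linear")
    return float(med), float(q1), float(q3)


# ---------------------------------------------------------------------------
# derived screening variables


def _safe_ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def derive_screening_variables(
    records: list[ScreeningRecord],
) -> tuple[dict[str, GroupedVariable], dict]:
    """Per-image derived variables, grouped by substrate.

    Undefined ratios (no unipolar cells, no cells of a polarity class, no
    neurites) propagate as missing values and are dropped per group; the
    QC log counts every exclusion.
    """
    per_image: list[dict] = []
    qc = {"excluded_images_no_cells": 0, "missing_values": {}}
    for rec in records:
        if rec.n_cells == 0:
            qc["excluded_images_no_cells"] += 1
            continue
        u, b, m = rec.n_unipolar, rec.n_bipolar, rec.n_multipolar
        per_image.append(
            {
                "pattern_name": rec.pattern_name,
                "differentiated_fraction": rec.n_cells_with_neurites / rec.n_cells,
                "b_u_ratio": _safe_ratio(b, u),
                "m_u_ratio": _safe_ratio(m, u),
                "branched_fraction_unipolar": _safe_ratio(rec.n_unipolar_branched, u),
                "branched_fraction_bipolar": _safe_ratio(rec.n_bipolar_branched, b),
                "branched_fraction_multipolar": _safe_ratio(rec.n_multipolar_branched, m),
                "mean_neurite_length_um": rec.mean_neurite_length_um,
                "n_neurites": float(rec.n_neurites),
                "alignment_vesselness": rec.alignment_vesselness,
                "alignment_fft": rec.alignment_fft,
                "alignment_chord": rec.alignment_chord,
            }
        )
    frame = pd.DataFrame(per_image)
    out: dict[str, GroupedVariable] = {}
    if frame.empty:
        return out, qc
    for name in frame.columns.drop("pattern_name"):
        groups: dict[str, np.ndarray] = {}
        n_missing = 0
        for pattern, sub in frame.groupby("pattern_name", sort=True):
            vals = sub[name].to_numpy(dtype=float)
            finite = vals[np.isfinite(vals)]
            n_missing += int(vals.size - finite.size)
            if finite.size:
                groups[pattern] = finite
        qc["missing_values"][name] = n_missing
        if groups:
            out[name] = GroupedVariable(name=name, groups=groups)
    return out, qc


def run_stats(
    variables: dict[str, GroupedVariable], alpha: float = 0.05, adjust: str = "bonferroni"
) -> list[StatsReport]:
    """The full per-variable battery; variables with < 2 groups are skipped."""
    reports = []
    for name, var in variables.items():
        labels = sorted(var.groups)
        groups = [var.groups[k] for k in labels]
        if len(groups) < 2 or sum(g.size for g in groups) < 5:
            continue
        lil = {}
        for lab, g in zip(labels, groups):
            if g.size >= 4 and np.ptp(g) > 0:
                lil[lab] = lilliefors(g)[1]
        h, p = kruskal_wallis(groups)
        dunn = dunns_posthoc(groups, labels=labels, alpha=alpha, adjust=adjust)
        med = {lab: summarize_median_iqr(g) for lab, g in zip(labels, groups)}
        reports.append(
            StatsReport(
                variable=name,
                lilliefors_p=lil,
                kruskal_h=h,
                kruskal_p=p,
                dunn=dunn,
                median_iqr=med,
                alpha=alpha,
            )
        )
    return reports
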