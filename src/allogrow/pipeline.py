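"""Per-group fits, cross-group comparisons, reports and plots.

The analysis question is whether maximum growth rates separate endotherms
from ectotherms once body mass and phylogeny are accounted for.  The
pipeline standardizes raw growth constants, fits each taxonomic group with
both a free slope and a slope fixed at the 3/4 value predicted by
metabolic scaling theory, and compares groups through their fixed-slope
intercepts: back-transformed normalization constants, pairwise fold
differences, confidence-interval overlap, and the spread of per-species
residual variation.
"""

from __future__ import annotations

import json
import logging
import math
import shutil
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import growth
from .pgls import PGLS, PGLSResults
from .trees import Phylogeny, expand_duplicate_tips, match_and_prune, read_newick, vcv_from_tree

log = logging.getLogger(__name__)

__all__ = [
    "GroupFitSummary",
    "ComparisonReport",
    "BoltzmannParams",
    "fit_group",
    "slope_consistency",
    "fold_difference",
    "intercept_overlap_matrix",
    "fold_matrix",
    "residual_variation",
    "box_stats",
    "boltzmann_ratio",
    "statistically_different",
    "run_pipeline",
]

THEORY_SLOPE = 0.75  # metabolic-theory prediction for rate-vs-mass scaling
SURFACE_SLOPE = 2.0 / 3.0  # surface-to-volume alternative


# ---------------------------------------------------------------------------
# group fitting


@dataclass
class GroupFitSummary:
    """All four fit variants for one group plus slope-consistency flags."""

    group: str
    n_pgls: int
    n_ols: int
    pgls_free: Optional[PGLSResults]
    pgls_fixed: Optional[PGLSResults]
    ols_free: PGLSResults
    ols_fixed: PGLSResults
    dropped_species: list[str] = field(default_factory=list)

    @property
    def fit_free(self) -> PGLSResults:
        """Preferred free-slope fit: phylogenetic when available."""
        return self.pgls_free if self.pgls_free is not None else self.ols_free

    @property
    def fit_fixed(self) -> PGLSResults:
        return self.pgls_fixed if self.pgls_fixed is not None else self.ols_fixed

    @property
    def slope_contains_075(self) -> bool:
        return slope_consistency(self.fit_free, THEORY_SLOPE)

    @property
    def slope_contains_067(self) -> bool:
        return slope_consistency(self.fit_free, SURFACE_SLOPE)

    @property
    def intercept_backtransform(self) -> float:
        return self.fit_fixed.normalization_constant


def fit_group(
    std: pd.DataFrame,
    tree: Optional[Phylogeny] = None,
    group: Optional[str] = None,
    fixed_slope: float = THEORY_SLOPE,
    restrict_lambda: bool = False,
    min_pgls: int = 4,
) -> GroupFitSummary:
    """Fit one group's standardized table with all four model variants.

    OLS uses every record.  PGLS uses the records whose species match a
    tree tip; groups that allow several records per species (repeated
    species names, e.g. dinosaur growth series) get a record-level
    covariance built by expanding the matching tips.  With no tree, or
    fewer than ``min_pgls`` matching records, the phylogenetic fits are
    skipped with a warning and the summary is OLS-only.
    """
    if group is not None:
        std = std[std["group"] == group]
    else:
        gs = std["group"].unique()
        if len(gs) != 1:
            raise ValueError("table spans multiple groups; pass group explicitly")
        group = gs[0]
    if not len(std):
        raise ValueError(f"no records for group {group!r}")
    y = std["log10_agr"].to_numpy()
    x = std["log10_bmatmg"].to_numpy()
    ols_free = PGLS(y, x).fit()
    ols_fixed = PGLS(y, x, fixed_slope=fixed_slope).fit()

    pgls_free = pgls_fixed = None
    n_pgls = 0
    dropped: list[str] = []
    if tree is not None:
        species = std["species"].tolist()
        uniq = list(dict.fromkeys(species))
        try:
            pruned, matched, dropped = match_and_prune(tree, uniq)
        except ValueError as err:
            warnings.warn(f"group {group}: {err}; falling back to OLS", stacklevel=2)
            pruned, matched = None, []
        if pruned is not None:
            matched_set = {growth.normalize_species_name(s) for s in matched}
            mask = std["species"].map(growth.normalize_species_name).isin(matched_set)
            sub = std[mask]
            n_pgls = len(sub)
            if n_pgls < min_pgls:
                warnings.warn(
                    f"group {group}: only {n_pgls} records match the tree; "
                    "phylogenetic fit skipped",
                    stacklevel=2,
                )
            else:
                rec_species = sub["species"].tolist()
                if len(set(rec_species)) < len(rec_species):
                    labels = [f"{sp}_r{i + 1}" for i, sp in enumerate(rec_species)]
                    expanded = expand_duplicate_tips(pruned, rec_species, labels=labels)
                    cov = vcv_from_tree(expanded, labels)
                else:
                    cov = vcv_from_tree(pruned, rec_species)
                ys, xs = sub["log10_agr"].to_numpy(), sub["log10_bmatmg"].to_numpy()
                pgls_free = PGLS(ys, xs, cov=cov, restrict_lambda=restrict_lambda).fit()
                pgls_fixed = PGLS(
                    ys, xs, cov=cov, fixed_slope=fixed_slope,
                    restrict_lambda=restrict_lambda,
                ).fit()
    else:
        log.info("group %s: no tree supplied; OLS only", group)
    return GroupFitSummary(
        group=group,
        n_pgls=n_pgls,
        n_ols=len(std),
        pgls_free=pgls_free,
        pgls_fixed=pgls_fixed,
        ols_free=ols_free,
        ols_fixed=ols_fixed,
        dropped_species=dropped,
    )


# ---------------------------------------------------------------------------
# comparisons


def slope_consistency(fit: PGLSResults, target: float = THEORY_SLOPE) -> bool:
    """Is ``target`` inside the free-slope fit's 95% CI (bounds inclusive)?"""
    lo, hi = fit.conf_int()[1]
    return bool(lo <= target <= hi)


def fold_difference(intercept_a: float, intercept_b: float) -> float:
    """Ratio of normalization constants: 10^(a - b) for log10 intercepts
    from same-slope fits."""
    return 10.0 ** (intercept_a - intercept_b)


def intercept_overlap_matrix(summaries: list[GroupFitSummary]) -> pd.DataFrame:
    """Boolean matrix: entry (A, B) is True when A's fixed-slope intercept
    point estimate lies inside B's 95% CI.  Asymmetric by construction —
    both directions are reported."""
    groups = [s.group for s in summaries]
    out = pd.DataFrame(False, index=groups, columns=groups)
    for a in summaries:
        for b in summaries:
            lo, hi = b.fit_fixed.conf_int()[0]
            out.loc[a.group, b.group] = bool(lo <= a.fit_fixed.intercept <= hi)
    return out


def fold_matrix(summaries: list[GroupFitSummary]) -> pd.DataFrame:
    """Pairwise normalization-constant ratios 10^(intercept_A - intercept_B)."""
    groups = [s.group for s in summaries]
    ints = {s.group: s.fit_fixed.intercept for s in summaries}
    return pd.DataFrame(
        [[fold_difference(ints[a], ints[b]) for b in groups] for a in groups],
        index=groups,
        columns=groups,
    )


def statistically_different(
    a: GroupFitSummary, b: GroupFitSummary, rule: str = "either"
) -> bool:
    """Are two groups' regressions statistically distinguishable?

    ``rule="either"`` (default): some coefficient of one model falls outside
    the other's CI in either direction — intercept and/or slope, matching
    the phrasing used in cross-group comparisons of allometries.
    ``rule="both"``: stricter — each model's intercept lies outside the
    other's intercept CI in both directions.
    """
    def outside(point, fit, which):
        lo, hi = fit.conf_int()[which]
        return not (lo <= point <= hi)

    a_free, b_free = a.fit_free, b.fit_free
    if rule == "both":
        return outside(a.fit_fixed.intercept, b.fit_fixed, 0) and outside(
            b.fit_fixed.intercept, a.fit_fixed, 0
        )
    if rule != "either":
        raise ValueError("rule must be 'either' or 'both'")
    return (
        outside(a_free.intercept, b_free, 0)
        or outside(b_free.intercept, a_free, 0)
        or outside(a_free.slope, b_free, 1)
        or outside(b_free.slope, a_free, 1)
    )


def residual_variation(fit: PGLSResults) -> np.ndarray:
    """Per-species residual plus the fit's intercept."""
    return fit.residual_variation()


def box_stats(values: np.ndarray) -> dict:
    """Box-plot summary with 1.5 x IQR whiskers (the R default): median,
    quartiles, whisker ends at the most extreme points inside the fences,
    and the outliers beyond them."""
    v = np.asarray(values, float)
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(inside.min()),
        "whisker_high": float(inside.max()),
        "outliers": [float(o) for o in v[(v < lo_fence) | (v > hi_fence)]],
        "mean": float(v.mean()),
        "n": int(v.size),
    }


@dataclass(frozen=True)
class BoltzmannParams:
    """Boltzmann-factor comparison of metabolic rates at two body
    temperatures: activation energy E (eV), Boltzmann constant (eV/K) and
    temperatures in Kelvin within the biologically plausible range."""

    E: float = 0.63
    k_boltz: float = 8.6173324e-5
    T_a: float = 314.0  # avian body temperature, 41 C
    T_b: float = 309.0  # mammalian body temperature, 36 C

    def __post_init__(self):
        if not (self.E >= 0 and self.k_boltz > 0):
            raise ValueError("E must be >= 0 and k_boltz positive")
        for T in (self.T_a, self.T_b):
            if not 270.0 <= T <= 330.0:
                raise ValueError(f"temperature {T} K outside plausible range 270-330 K")


def boltzmann_ratio(params: BoltzmannParams = BoltzmannParams()) -> float:
    """exp(-E/(k T_a)) / exp(-E/(k T_b)): the metabolic-rate ratio predicted
    from body-temperature difference alone."""
    return math.exp(-params.E / (params.k_boltz * params.T_a)) / math.exp(
        -params.E / (params.k_boltz * params.T_b)
    )


# ---------------------------------------------------------------------------
# report


@dataclass
class ComparisonReport:
    """Cross-group comparison: per-group fits, overlap/fold matrices,
    residual variation, and the intercept ranking."""

    summaries: list[GroupFitSummary]

    @property
    def ranking(self) -> list[str]:
        """Groups ordered from highest to lowest fixed-slope intercept."""
        return [
            s.group
            for s in sorted(self.summaries, key=lambda s: -s.fit_fixed.intercept)
        ]

    def overlap(self) -> pd.DataFrame:
        return intercept_overlap_matrix(self.summaries)

    def folds(self) -> pd.DataFrame:
        return fold_matrix(self.summaries)

    def residual_summary(self) -> dict[str, dict]:
        return {
            s.group: box_stats(residual_variation(s.fit_fixed)) for s in self.summaries
        }

    def free_slope_table(self) -> pd.DataFrame:
        """Per-group free-slope fits: n, intercept and slope with CIs,
        lambda, AIC."""
        rows = []
        for s in sorted(self.summaries, key=lambda s: -s.fit_free.intercept):
            f = s.fit_free
            ci = f.conf_int()
            pv = f.pvalues
            rows.append(
                {
                    "group": s.group,
                    "N": f.nobs,
                    "intercept": f.intercept,
                    "intercept_ci_low": ci[0, 0],
                    "intercept_ci_high": ci[0, 1],
                    "intercept_p": pv[0],
                    "slope": f.slope,
                    "slope_ci_low": ci[1, 0],
                    "slope_ci_high": ci[1, 1],
                    "slope_p": pv[1],
                    "lambda": f.lambda_,
                    "AIC": f.aic,
                    "contains_075": slope_consistency(f, THEORY_SLOPE),
                    "contains_067": slope_consistency(f, SURFACE_SLOPE),
                    "variant": f.variant,
                }
            )
        return pd.DataFrame(rows)

    def fixed_slope_table(self) -> pd.DataFrame:
        """Per-group fixed-slope fits: intercept with CI, lambda, AIC, and
        the back-transformed normalization constant 10^intercept."""
        rows = []
        for s in sorted(self.summaries, key=lambda s: -s.fit_fixed.intercept):
            f = s.fit_fixed
            ci = f.conf_int()
            rows.append(
                {
                    "group": s.group,
                    "N": f.nobs,
                    "intercept": f.intercept,
                    "intercept_ci_low": ci[0, 0],
                    "intercept_ci_high": ci[0, 1],
                    "intercept_p": f.pvalues[0],
                    "lambda": f.lambda_,
                    "AIC": f.aic,
                    "norm_constant": f.normalization_constant,
                    "variant": f.variant,
                }
            )
        return pd.DataFrame(rows)

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.free_slope_table().to_csv(out / "fits_free_slope.csv", index=False)
        self.fixed_slope_table().to_csv(out / "fits_fixed_slope.csv", index=False)
        self.overlap().to_csv(out / "intercept_overlap.csv")
        self.folds().to_csv(out / "fold_differences.csv")
        (out / "residual_variation.json").write_text(
            json.dumps(self.residual_summary(), indent=2)
        )
        (out / "fits.json").write_text(
            json.dumps(
                {
                    s.group: {
                        v: (getattr(s, v).to_dict() if getattr(s, v) is not None else None)
                        for v in ("pgls_free", "pgls_fixed", "ols_free", "ols_fixed")
                    }
                    for s in self.summaries
                },
                indent=2,
            )
        )


# ---------------------------------------------------------------------------
# plots


def plot_allometry(std: pd.DataFrame, report: ComparisonReport, path) -> None:
    """Log-log scatter of AGR against BMatMG with the fixed-slope regression
    line of each group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 6))
    for s in report.summaries:
        sub = std[std["group"] == s.group]
        pts = ax.scatter(sub["log10_bmatmg"], sub["log10_agr"], s=12, alpha=0.6,
                         label=f"{s.group} (n={s.n_ols})")
        xs = np.linspace(sub["log10_bmatmg"].min(), sub["log10_bmatmg"].max(), 2)
        f = s.fit_fixed
        ax.plot(xs, f.intercept + f.slope * xs, color=pts.get_facecolor()[0], lw=1.5)
    ax.set_xlabel("log10 body mass at maximum growth (g)")
    ax.set_ylabel("log10 maximum growth rate (g/day)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_residual_variation(report: ComparisonReport, path) -> None:
    """Box plots (1.5 x IQR whiskers) of residual variation per group, with
    each group's intercept marked."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    groups = report.ranking
    data = {s.group: residual_variation(s.fit_fixed) for s in report.summaries}
    ax.boxplot([data[g] for g in groups], tick_labels=groups, whis=1.5, showmeans=True)
    for i, s in enumerate(sorted(report.summaries, key=lambda s: -s.fit_fixed.intercept)):
        ax.hlines(s.fit_fixed.intercept, i + 0.7, i + 1.3, colors="red", lw=1)
    ax.set_ylabel("residuals + intercept (log10 g/day)")
    plt.setp(ax.get_xticklabels(), rotation=45, ha="right", fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# orchestration


def run_pipeline(config: dict, outdir=None) -> ComparisonReport:
    """Standardize, fit and compare every group in a configuration.

    ``config`` keys: ``trait_table`` (path to the raw CSV), optional
    ``trees`` (mapping group -> Newick path), optional ``fixed_slope``
    (default 0.75), ``restrict_lambda``, ``aggregate`` (default True),
    ``plots`` (default True when writing).  Outputs are deterministic given
    the same inputs; on any stage failure partial outputs are removed.
    """
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    try:
        records = growth.read_trait_table(config["trait_table"])
        if not records:
            raise ValueError("trait table is empty")
        std = growth.standardize_table(records, aggregate=config.get("aggregate", True))
        trees = {
            g: read_newick(p) for g, p in (config.get("trees") or {}).items()
        }
        summaries = []
        matched_report = []
        for g in sorted(std["group"].unique()):
            s = fit_group(
                std,
                tree=trees.get(g),
                group=g,
                fixed_slope=config.get("fixed_slope", THEORY_SLOPE),
                restrict_lambda=config.get("restrict_lambda", False),
            )
            summaries.append(s)
            matched_report.append(
                f"{g}: {s.n_pgls} records in phylogenetic fit, {s.n_ols} in OLS; "
                f"dropped from tree matching: {', '.join(s.dropped_species) or 'none'}"
            )
        report = ComparisonReport(summaries)
        if outdir is not None:
            growth.write_standardized_table(std, outdir / "standardized.csv")
            report.write(outdir)
            (outdir / "matching_report.txt").write_text("\n".join(matched_report) + "\n")
            if config.get("plots", True):
                plot_allometry(std, report, outdir / "allometry.png")
                plot_residual_variation(report, outdir / "residual_variation.png")
        return report
    except Exception as err:
        if outdir is not None and outdir.exists():
            shutil.rmtree(outdir, ignore_errors=True)
        raise RuntimeError(f"pipeline failed: {err}") from err
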