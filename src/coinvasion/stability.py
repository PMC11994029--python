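"""Stability classification and single- vs co-invasion comparison.

Statistical stage of the invasion-criterion analysis.  Three questions:

1. **Is each community stable?**  One two-sided one-sample t-test per
   treatment (focal x resident community) against the null that mean RGR
   equals 1, Benjamini-Hochberg FDR across the whole battery; a treatment
   is called *stable* when its mean RGR exceeds 1 AND the adjusted p falls
   below alpha.
2. **Do single-invasion RGRs predict co-invasion RGRs?**  Per-species
   Spearman rank correlations of paired treatment means (FDR across
   species), and an OLS of co-invasion mean on single-invasion mean
   crossed with species identity, with nested-model F-tests for the
   interaction, species-intercept and common-slope terms.
3. **Within each resident community, does invasion type matter?**  A
   treatment x invasion-type factorial fit on replicate-level RGRs, a
   global interaction F, and one multiplicity-adjusted contrast per paired
   treatment.

The module exposes both the individual operations (:func:`classify`,
:func:`bh_fdr`, :func:`correlate_by_species`, :func:`fit_interaction_model`,
:func:`within_treatment_contrasts`) and two model objects wrapping them,
:class:`StabilityModel` and :class:`SingleVsCoModel`, whose ``fit()``
returns results objects with ``summary()`` tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "bh_fdr",
    "classify",
    "correlate_by_species",
    "fit_interaction_model",
    "within_treatment_contrasts",
    "InteractionModelFit",
    "ContrastResult",
    "CollinearityError",
    "StabilityModel",
    "StabilityResults",
    "SingleVsCoModel",
    "SingleVsCoResults",
    "paired_means",
    "CALL_COLUMNS",
]


class CollinearityError(ValueError):
    """Rank-deficient design matrix in a comparison model."""


CALL_COLUMNS = (
    "treatment_id",
    "focal",
    "residents",
    "co_invaders",
    "invasion_type",
    "n_replicates",
    "mean_rgr",
    "t_statistic",
    "df",
    "p_raw",
    "p_adjusted",
    "stable",
    "untestable",
)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Sorts ascending, takes ``q_(i) = min_{j>=i} p_(j) * m / j`` capped at
    1, and returns values in the original order.  Controls the expected
    fraction of false discoveries among rejections at any threshold.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def classify(
    rgr_table: pd.DataFrame,
    alpha: float = 0.05,
    adjust: str = "fdr",
    null_rgr: float = 1.0,
) -> pd.DataFrame:
    """One stability call per treatment from replicate-level RGRs.

    Each treatment group gets a two-sided one-sample t-test of its defined
    RGR values against ``null_rgr``; the whole battery is BH-adjusted
    (``adjust="fdr"``) or left raw (``"none"``).  Groups with fewer than
    two defined values or zero variance are reported *untestable* — their
    mean is still shown and they are never called stable — so the output
    always has one row per treatment in the input.
    """
    if adjust not in ("fdr", "none"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    if rgr_table.empty:
        raise ValueError("empty RGR table")
    rows = []
    for tid, grp in rgr_table.groupby("treatment_id", sort=False):
        vals = grp["rgr"].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        n = vals.size
        mean = float(np.mean(vals)) if n else np.nan
        sd = float(np.std(vals, ddof=1)) if n >= 2 else np.nan
        if n >= 2 and sd > 0:
            t_stat, p_raw = sps.ttest_1samp(vals, popmean=null_rgr)
            t_stat, p_raw, df, untestable = float(t_stat), float(p_raw), n - 1, False
        else:
            t_stat, p_raw, df, untestable = np.nan, np.nan, np.nan, True
        first = grp.iloc[0]
        rows.append(
            {
                "treatment_id": tid,
                "focal": first.get("focal", ""),
                "residents": first.get("residents", ""),
                "co_invaders": first.get("co_invaders", ""),
                "invasion_type": first.get("invasion_type", ""),
                "n_replicates": n,
                "mean_rgr": mean,
                "t_statistic": t_stat,
                "df": df,
                "p_raw": p_raw,
                "untestable": untestable,
            }
        )
    calls = pd.DataFrame(rows)
    calls["p_adjusted"] = np.nan
    tested = ~calls["untestable"]
    if tested.any():
        p = calls.loc[tested, "p_raw"].to_numpy()
        calls.loc[tested, "p_adjusted"] = bh_fdr(p) if adjust == "fdr" else p
    calls["stable"] = (
        tested & (calls["mean_rgr"] > null_rgr) & (calls["p_adjusted"] < alpha)
    )
    return calls[list(CALL_COLUMNS)]


def correlate_by_species(paired: pd.DataFrame, adjust: str = "fdr") -> pd.DataFrame:
    """Per-species Spearman correlation of single- vs co-invasion means.

    ``paired`` needs columns ``species, mean_rgr_single, mean_rgr_co``.
    Rank correlation uses average ranks on ties; p-values come from the
    t-distribution approximation to the null of exchangeable ranks (the
    standard large-sample treatment).  Species with fewer than 3 pairs or
    a constant vector are flagged undefined; FDR is applied across the
    defined species tests.
    """
    rows = []
    for species, grp in paired.groupby("species", sort=True):
        x = grp["mean_rgr_single"].to_numpy(dtype=float)
        y = grp["mean_rgr_co"].to_numpy(dtype=float)
        keep = np.isfinite(x) & np.isfinite(y)
        x, y = x[keep], y[keep]
        flag = ""
        if x.size < 3:
            rho = p = np.nan
            flag = "too_few_pairs"
        elif np.all(x == x[0]) or np.all(y == y[0]):
            rho = p = np.nan
            flag = "constant_vector"
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rho, p = sps.spearmanr(x, y)
            rho, p = float(rho), float(p)
            if not np.isfinite(rho):
                rho = p = np.nan
                flag = "undefined"
        rows.append(
            {"species": species, "n_pairs": int(x.size), "rho": rho,
             "p_raw": p, "flag": flag}
        )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = np.nan
    ok = out["p_raw"].notna()
    if ok.any():
        p = out.loc[ok, "p_raw"].to_numpy()
        out.loc[ok, "p_adjusted"] = bh_fdr(p) if adjust == "fdr" else p
    return out[["species", "n_pairs", "rho", "p_raw", "p_adjusted", "flag"]]


@dataclass
class InteractionModelFit:
    """OLS of co-invasion mean RGR on single-invasion mean x species.

    Term significance comes from nested-model comparisons: the full
    (interaction) model against the additive model for the interaction
    term, and the additive model against models dropping the species
    intercepts or the common slope.  ``method="f"`` uses the exact
    Gaussian-OLS F-test on residual sums of squares; ``"chi2"`` the
    large-sample likelihood-ratio chi-square.
    """

    slope: float
    intercepts: pd.Series  # per-species intercepts (additive model)
    per_species_slopes: pd.Series  # from the full interaction model
    terms: pd.DataFrame  # term, statistic, df_num, df_den, p
    full_model: object = field(repr=False, default=None)
    additive_model: object = field(repr=False, default=None)


def _nested_test(reduced, full, method: str):
    """Compare nested OLS fits; returns (stat, df_num, df_den, p)."""
    df_num = full.df_model - reduced.df_model
    # a reduced model that already fits to numerical precision leaves the
    # extra term nothing to explain: report a null comparison instead of
    # the 0/0 statistic
    scale = max(float(full.centered_tss), np.finfo(float).tiny)
    if float(reduced.ssr) <= 1e-12 * scale:
        dfd = float(full.df_resid) if method == "f" else np.nan
        return 0.0, float(df_num), dfd, 1.0
    if method == "f":
        f, p, _ = full.compare_f_test(reduced)
        return float(f), float(df_num), float(full.df_resid), float(p)
    if method == "chi2":
        lr, p, _ = full.compare_lr_test(reduced)
        return float(lr), float(df_num), np.nan, float(p)
    raise ValueError(f"unknown method {method!r}")


def fit_interaction_model(
    paired: pd.DataFrame, method: str = "f"
) -> InteractionModelFit:
    """Fit mean_rgr_co ~ mean_rgr_single * species and test its terms.

    Needs >= 2 species and >= 3 points per species.  Raises
    :class:`CollinearityError` on a rank-deficient design, naming the
    aliased columns.
    """
    data = paired.dropna(subset=["mean_rgr_single", "mean_rgr_co"]).copy()
    counts = data.groupby("species").size()
    if len(counts) < 2:
        raise ValueError("need at least 2 species")
    if (counts < 3).any():
        few = counts[counts < 3].index.tolist()
        raise ValueError(f"need >= 3 points per species; too few for {few}")

    full = smf.ols("mean_rgr_co ~ mean_rgr_single * C(species)", data=data).fit()
    rank = np.linalg.matrix_rank(full.model.exog)
    if rank < full.model.exog.shape[1]:
        # aliased columns show up as ~0 diagonals in the QR factor
        diag = np.abs(np.diag(np.linalg.qr(full.model.exog, mode="r")))
        tol = diag.max() * 1e-10
        aliased = [
            full.model.exog_names[i] for i in range(len(diag)) if diag[i] < tol
        ]
        raise CollinearityError(f"rank-deficient design; aliased terms: {aliased}")

    additive = smf.ols("mean_rgr_co ~ mean_rgr_single + C(species)", data=data).fit()
    no_species = smf.ols("mean_rgr_co ~ mean_rgr_single", data=data).fit()
    no_slope = smf.ols("mean_rgr_co ~ C(species)", data=data).fit()

    terms = []
    for name, reduced, fullm in (
        ("interaction", additive, full),
        ("species", no_species, additive),
        ("slope", no_slope, additive),
    ):
        stat, dfn, dfd, p = _nested_test(reduced, fullm, method)
        terms.append(
            {"term": name, "statistic": stat, "df_num": dfn, "df_den": dfd, "p": p}
        )

    species = sorted(data["species"].unique())
    base = species[0]
    add_params = additive.params
    intercepts = pd.Series(
        {
            s: add_params["Intercept"]
            + (add_params.get(f"C(species)[T.{s}]", 0.0) if s != base else 0.0)
            for s in species
        },
        name="intercept",
    )
    full_params = full.params
    slopes = pd.Series(
        {
            s: full_params["mean_rgr_single"]
            + (
                full_params.get(f"mean_rgr_single:C(species)[T.{s}]", 0.0)
                if s != base
                else 0.0
            )
            for s in species
        },
        name="slope",
    )
    return InteractionModelFit(
        slope=float(add_params["mean_rgr_single"]),
        intercepts=intercepts,
        per_species_slopes=slopes,
        terms=pd.DataFrame(terms),
        full_model=full,
        additive_model=additive,
    )


@dataclass
class ContrastResult:
    """Factorial treatment x invasion-type fit with per-treatment contrasts."""

    table: pd.DataFrame  # one row per paired treatment
    interaction_F: float
    interaction_df: tuple[float, float]
    interaction_p: float
    residual_df: float
    mse: float


def within_treatment_contrasts(
    rgr_paired: pd.DataFrame,
    adjust: str = "fdr",
    alpha: float = 0.05,
) -> ContrastResult:
    """Invasion-type contrasts within each paired resident community.

    ``rgr_paired`` holds replicate-level RGRs with columns ``pair_id,
    invasion_type, rgr`` where both invasion types of a pair share the
    ``pair_id``.  Fits the full factorial (cell-means) model by OLS,
    reports the global pair x type interaction F against the additive
    model, and one contrast per pair (co mean minus single mean) using the
    factorial model's pooled residual variance, adjusted across pairs by
    Benjamini-Hochberg (``"fdr"``), Bonferroni (``"bonferroni"``) or not
    at all (``"none"``).

    Pairs lacking both invasion types with >= 2 defined replicates each
    are excluded with a warning naming them.
    """
    if adjust not in ("fdr", "bonferroni", "none"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    data = rgr_paired.dropna(subset=["rgr"]).copy()
    ok_pairs = []
    dropped = []
    for pid, grp in data.groupby("pair_id", sort=False):
        ns = grp.groupby("invasion_type").size()
        if ns.get("single", 0) >= 2 and ns.get("co", 0) >= 2:
            ok_pairs.append(pid)
        else:
            dropped.append(pid)
    if dropped:
        warnings.warn(
            f"excluding {len(dropped)} unpaired/underreplicated treatments: "
            f"{dropped}",
            stacklevel=2,
        )
    if not ok_pairs:
        raise ValueError("no testable pairs")
    data = data[data["pair_id"].isin(ok_pairs)]

    full = smf.ols("rgr ~ C(pair_id) * C(invasion_type)", data=data).fit()
    additive = smf.ols("rgr ~ C(pair_id) + C(invasion_type)", data=data).fit()
    f_int, p_int, df_num = full.compare_f_test(additive)
    mse = float(full.mse_resid)
    df_resid = float(full.df_resid)

    cells = data.groupby(["pair_id", "invasion_type"])["rgr"].agg(["mean", "size"])
    rows = []
    for pid in ok_pairs:
        m_co, n_co = cells.loc[(pid, "co")]
        m_s, n_s = cells.loc[(pid, "single")]
        diff = float(m_co - m_s)
        se = float(np.sqrt(mse * (1.0 / n_co + 1.0 / n_s)))
        t = diff / se
        p = 2.0 * float(sps.t.sf(abs(t), df_resid))
        rows.append(
            {"pair_id": pid, "diff_co_minus_single": diff, "se": se,
             "t_statistic": t, "df": df_resid, "p_raw": p}
        )
    table = pd.DataFrame(rows)
    if adjust == "fdr":
        table["p_adjusted"] = bh_fdr(table["p_raw"].to_numpy())
    elif adjust == "bonferroni":
        table["p_adjusted"] = np.minimum(table["p_raw"] * len(table), 1.0)
    else:
        table["p_adjusted"] = table["p_raw"]
    table["significant"] = table["p_adjusted"] < alpha
    return ContrastResult(
        table=table,
        interaction_F=float(f_int),
        interaction_df=(float(df_num), df_resid),
        interaction_p=float(p_int),
        residual_df=df_resid,
        mse=mse,
    )


# --------------------------------------------------------------------------
# Model / Results objects
# --------------------------------------------------------------------------


def paired_means(
    rgr_co: pd.DataFrame, rgr_single: pd.DataFrame, pairs
) -> pd.DataFrame:
    """Per-pair mean RGRs for the single- vs co-invasion comparison.

    ``pairs`` is an iterable of ``(co_treatment_id, single_treatment_id)``
    (or TreatmentSpec pairs).  The species column is the shared focal
    invader; means are over defined replicate RGRs.
    """
    def _mean(df, tid):
        grp = df[df["treatment_id"] == tid]
        vals = grp["rgr"].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        return float(vals.mean()) if vals.size else np.nan

    co_meta = rgr_co.drop_duplicates("treatment_id").set_index("treatment_id")
    rows = []
    for co, single in pairs:
        co_id = getattr(co, "treatment_id", co)
        single_id = getattr(single, "treatment_id", single)
        meta = co_meta.loc[co_id]
        rows.append(
            {
                "pair_id": co_id,
                "single_id": single_id,
                "species": meta["focal"],
                "residents": meta["residents"],
                "mean_rgr_single": _mean(rgr_single, single_id),
                "mean_rgr_co": _mean(rgr_co, co_id),
            }
        )
    return pd.DataFrame(rows)


class StabilityModel:
    """One-sample t-test battery over a replicate-level RGR table.

    Parameters
    ----------
    rgr_table : DataFrame
        Replicate-level RGR estimates (schema of ``growth.compute_all``).
    null_rgr : float
        The null mean RGR; 1 marks neutral frequency dependence.
    """

    def __init__(self, rgr_table: pd.DataFrame, null_rgr: float = 1.0):
        self.rgr_table = rgr_table
        self.null_rgr = null_rgr

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "StabilityModel":
        return cls(df, **kwargs)

    def fit(self, alpha: float = 0.05, adjust: str = "fdr") -> "StabilityResults":
        calls = classify(self.rgr_table, alpha=alpha, adjust=adjust,
                         null_rgr=self.null_rgr)
        return StabilityResults(self, calls, alpha, adjust)


class StabilityResults:
    """Stability calls with multiplicity-corrected verdicts."""

    def __init__(self, model, calls, alpha, adjust):
        self.model = model
        self.calls = calls
        self.alpha = alpha
        self.adjust = adjust

    @property
    def n_tests(self) -> int:
        return int((~self.calls["untestable"]).sum())

    @property
    def n_stable(self) -> int:
        return int(self.calls["stable"].sum())

    def by_focal(self) -> pd.DataFrame:
        """Per-focal-species stable/tested breakdown ('x out of 14' style)."""
        g = self.calls.groupby("focal", sort=True)
        return pd.DataFrame(
            {
                "n_stable": g["stable"].sum().astype(int),
                "n_tested": g.apply(
                    lambda d: int((~d["untestable"]).sum()), include_groups=False
                ),
                "n_untestable": g["untestable"].sum().astype(int),
                "n_treatments": g.size(),
            }
        ).reset_index()

    def summary(self) -> str:
        lines = [
            "Stability classification (one-sample t vs RGR = "
            f"{self.model.null_rgr:g}, adjust={self.adjust}, "
            f"alpha={self.alpha:g})",
            f"  treatments: {len(self.calls)}   tests performed: {self.n_tests}"
            f"   stable: {self.n_stable}"
            f"   untestable: {int(self.calls['untestable'].sum())}",
            "",
            self.by_focal().to_string(index=False),
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        from .plotting import plot_rgr_by_treatment

        return plot_rgr_by_treatment(self.model.rgr_table, self.calls, ax=ax)


class SingleVsCoModel:
    """Single- vs co-invasion comparison over paired treatments.

    Built from the two replicate-level RGR tables and the pairing between
    co-invasion treatments and their single-invasion counterparts sharing
    the same focal species and resident community.
    """

    def __init__(self, rgr_co: pd.DataFrame, rgr_single: pd.DataFrame, pairs):
        self.rgr_co = rgr_co
        self.rgr_single = rgr_single
        self.pairs = list(pairs)
        self.means = paired_means(rgr_co, rgr_single, self.pairs)

    def _contrast_data(self) -> pd.DataFrame:
        frames = []
        for co, single in self.pairs:
            co_id = getattr(co, "treatment_id", co)
            single_id = getattr(single, "treatment_id", single)
            a = self.rgr_co[self.rgr_co["treatment_id"] == co_id][
                ["replicate", "rgr"]
            ].assign(pair_id=co_id, invasion_type="co")
            b = self.rgr_single[self.rgr_single["treatment_id"] == single_id][
                ["replicate", "rgr"]
            ].assign(pair_id=co_id, invasion_type="single")
            frames.append(a)
            frames.append(b)
        return pd.concat(frames, ignore_index=True)

    def fit(
        self,
        alpha: float = 0.05,
        adjust: str = "fdr",
        method: str = "f",
    ) -> "SingleVsCoResults":
        correlations = correlate_by_species(self.means, adjust=adjust)
        interaction = fit_interaction_model(self.means, method=method)
        contrasts = within_treatment_contrasts(
            self._contrast_data(), adjust=adjust, alpha=alpha
        )
        return SingleVsCoResults(self, correlations, interaction, contrasts)


class SingleVsCoResults:
    """Correlations, factorial model terms and per-treatment contrasts."""

    def __init__(self, model, correlations, interaction, contrasts):
        self.model = model
        self.correlations = correlations
        self.interaction = interaction
        self.contrasts = contrasts

    def summary(self) -> str:
        t = self.interaction.terms
        lines = [
            "Single- vs co-invasion comparison "
            f"({len(self.model.means)} paired treatments)",
            "",
            "Per-species Spearman correlations:",
            self.correlations.to_string(index=False),
            "",
            f"Common slope (additive OLS): {self.interaction.slope:.4f}",
            "Nested-model term tests:",
            t.to_string(index=False),
            "",
            f"Treatment x invasion-type interaction: "
            f"F({self.contrasts.interaction_df[0]:.0f}, "
            f"{self.contrasts.interaction_df[1]:.0f}) = "
            f"{self.contrasts.interaction_F:.3f}, "
            f"p = {self.contrasts.interaction_p:.4g}",
            f"Significant per-treatment contrasts: "
            f"{int(self.contrasts.table['significant'].sum())} of "
            f"{len(self.contrasts.table)}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        from .plotting import plot_single_vs_co

        return plot_single_vs_co(self.model.means, ax=ax)
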