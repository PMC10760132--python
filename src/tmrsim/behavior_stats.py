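"""Mixed-effects model suite for pre/post-nap feature memory.

The primary model predicts an item's accuracy change across the nap from
cueing status, feature type, their interaction, the (mean-centered) number of
cue repetitions, and pre-nap accuracy, with a per-subject random intercept:

    accuracy_difference ~ cueing * feature_type + times_cued_c
                          + prenap_accuracy + (1 | subject)

Variants swap the cueing term for richer codings (spread to uncued category
mates, sleep stage of cueing, blocked vs interleaved style, blocked sequence
position, or an evoked-power covariate) with the corresponding inclusion
filters. Fitting is delegated to statsmodels' MixedLM; the bespoke content
is the condition coding, the inclusion filters, and the contrasts.

Coefficient tests use a normal approximation to the sampling distribution
(``ModelResult.df_method == "normal"``); marginal-mean pairwise comparisons
are Tukey-adjusted via the studentized range.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

VARIANTS = ("primary", "spread", "stage", "style", "seqpos_numeric",
            "seqpos_categorical", "power_theta", "power_spindle", "novel")


class DegenerateDesignError(ValueError):
    """A required design cell is empty after filtering."""


@dataclass(frozen=True)
class ModelSpec:
    """Which model to fit and which rows it may use."""

    variant: str = "primary"
    outcome: str = "accuracy_difference"
    min_cues_for_style: int = 4
    include_uncued_in_style: bool = False
    shared_ge_unique_subset: bool = False

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")


@dataclass
class ModelResult:
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    cov: pd.DataFrame
    formula: str
    n_obs: int
    n_subjects: int
    converged: bool
    df_method: str = "normal"
    emmeans: pd.DataFrame | None = None
    contrasts: pd.DataFrame | None = None
    residual_summary: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> float:
        return float(self.params[name])


# ---------------------------------------------------------------------------
# Frame preparation
# ---------------------------------------------------------------------------

def prepare_model_frame(dataset: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Apply the variant's inclusion filters and condition coding.

    Items count as *cued* only if they are in a cued category and were cued
    at least once; never-cued items of cued categories are the *spread*
    model's middle level and are excluded from the other cueing codings.
    ``times_cued_c`` is mean-centered within the returned frame.
    """
    df = dataset.copy()
    v = spec.variant
    if v == "novel":
        df = df[df["is_novel"]]
    else:
        df = df[~df["is_novel"]]

    if spec.shared_ge_unique_subset and v != "novel":
        wide = (df.pivot_table(index=["subject", "item"],
                               columns="feature_type",
                               values="prenap_accuracy"))
        if "unique" in wide:
            keep = wide[wide["shared"] >= wide["unique"]].index
            df = df.set_index(["subject", "item"])
            df = df.loc[df.index.isin(keep)].reset_index()

    if v in ("primary", "novel"):
        df = df[df["cue_condition"].isin(["cued", "uncued"])]
        df["cueing"] = pd.Categorical(df["cue_condition"],
                                      categories=["uncued", "cued"])
        term = "cueing"
    elif v == "spread":
        df["cueing"] = pd.Categorical(
            df["cue_condition"].map({"uncued": "uncued_uncued",
                                     "uncued_in_cued": "uncued_cued",
                                     "cued": "cued_cued"}),
            categories=["uncued_uncued", "uncued_cued", "cued_cued"])
        term = "cueing"
    elif v == "stage":
        df = df[df["cue_condition"].isin(["cued", "uncued"])]
        df["cueing"] = pd.Categorical(
            np.where(df["cue_condition"] == "uncued", "uncued",
                     df["cue_stage"]),
            categories=["uncued", "N2", "N3", "both"])
        term = "cueing"
    elif v == "style":
        cued = ((df["cue_condition"] == "cued")
                & (df["times_cued"] >= spec.min_cues_for_style))
        if spec.include_uncued_in_style:
            df = df[cued | (df["cue_condition"] == "uncued")]
            lab = np.where(df["cue_condition"] == "uncued", "uncued",
                           df["order_condition"])
            df["cueing"] = pd.Categorical(
                lab, categories=["uncued", "interleaved", "blocked"])
        else:
            df = df[cued]
            df["cueing"] = pd.Categorical(
                df["order_condition"], categories=["interleaved", "blocked"])
        term = "cueing"
    elif v.startswith("seqpos"):
        blocked_full = ((df["order_condition"] == "blocked")
                        & (df["cue_condition"] == "cued")
                        & df["sequence_position"].notna())
        uncued = df["cue_condition"] == "uncued"
        df = df[blocked_full | uncued]
        df["sequence_position"] = df["sequence_position"].fillna(0).astype(int)
        term = "sequence_position"
        if v == "seqpos_categorical":
            df["sequence_position"] = pd.Categorical(
                df["sequence_position"], categories=[0, 1, 2, 3, 4])
    elif v.startswith("power"):
        df = df[df["cue_condition"] == "cued"]
        term = "theta_power" if v == "power_theta" else "spindle_power"
        df = df[df[term].notna()]
    else:  # pragma: no cover
        raise AssertionError(v)

    df = df[df[spec.outcome].notna()]
    if df.empty:
        raise DegenerateDesignError("no rows left after filtering")
    if isinstance(df.get("cueing"), pd.Series) and hasattr(df["cueing"], "cat"):
        counts = df["cueing"].value_counts()
        empty = [str(lv) for lv in counts.index[counts == 0]]
        if empty:
            raise DegenerateDesignError(
                f"empty design level(s) after filtering: {empty}")
    df["times_cued_c"] = df["times_cued"] - df["times_cued"].mean()
    df.attrs["term"] = term
    df.attrs["spec"] = spec
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _formula(frame: pd.DataFrame, spec: ModelSpec) -> str:
    term = frame.attrs["term"]
    out = spec.outcome
    pre = ("prenap_confidence" if out.startswith("confidence")
           else "prenap_accuracy")
    v = spec.variant
    if v == "novel":
        return f"{out} ~ cueing + times_cued_c + {pre}"
    if v.startswith("seqpos"):
        # fully cued items only, so the repetition covariate is dropped
        return f"{out} ~ {term} * feature_type + {pre}"
    if v.startswith("power"):
        return f"{out} ~ {term} * feature_type + times_cued_c + {pre}"
    return f"{out} ~ {term} * feature_type + times_cued_c + {pre}"


def _fit(frame: pd.DataFrame, formula: str) -> ModelResult:
    if frame["subject"].nunique() < 2:
        raise DegenerateDesignError("need at least 2 subjects")
    model = smf.mixedlm(formula, data=frame, groups=frame["subject"])
    # the default optimizer can silently fail near a singular random-effect
    # covariance (non-finite or degraded REML criterion); fit with two
    # optimizers and keep the better finite REML log-likelihood
    fits = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in (None, "powell"):
            try:
                f = (model.fit(reml=True) if method is None
                     else model.fit(reml=True, method=method))
            except (np.linalg.LinAlgError, ValueError):
                continue
            if np.isfinite(f.llf):
                fits.append(f)
    if not fits:
        raise DegenerateDesignError("mixed-model fit failed to converge")
    fit = max(fits, key=lambda f: f.llf)
    k = len(fit.fe_params)
    try:
        resid = np.asarray(fit.resid)
    except (ValueError, np.linalg.LinAlgError):
        # singular random-effect covariance: fall back to marginal residuals
        resid = (np.asarray(fit.model.endog)
                 - fit.model.exog @ np.asarray(fit.fe_params))
    return ModelResult(
        params=fit.fe_params,
        bse=fit.bse_fe,
        tvalues=fit.fe_params / fit.bse_fe,
        pvalues=pd.Series(
            2 * stats.norm.sf(np.abs(fit.fe_params / fit.bse_fe)),
            index=fit.fe_params.index),
        cov=fit.cov_params().iloc[:k, :k],
        formula=formula,
        n_obs=int(fit.nobs),
        n_subjects=int(frame["subject"].nunique()),
        converged=bool(fit.converged),
        residual_summary={
            "mean": float(resid.mean()), "sd": float(resid.std()),
            "skew": float(stats.skew(resid)),
            "kurtosis": float(stats.kurtosis(resid)),
        },
    )


def fit_primary_model(frame: pd.DataFrame) -> ModelResult:
    """Fit the primary cueing x feature-type model and attach marginal-mean
    contrasts (cued vs uncued within feature type; shared vs unique within
    cueing level), Tukey-adjusted."""
    spec: ModelSpec = frame.attrs.get("spec", ModelSpec())
    res = _fit(frame, _formula(frame, spec))
    if frame.attrs["term"] == "cueing" and "feature_type" in frame:
        res.emmeans, res.contrasts = estimated_marginal_means(
            res, frame, "cueing", "feature_type")
    return res


def fit_variant_model(frame: pd.DataFrame,
                      spec: ModelSpec | None = None) -> ModelResult:
    spec = spec or frame.attrs.get("spec", ModelSpec())
    res = _fit(frame, _formula(frame, spec))
    term = frame.attrs["term"]
    if (term == "cueing" and "feature_type" in frame
            and spec.variant != "novel"):
        res.emmeans, res.contrasts = estimated_marginal_means(
            res, frame, "cueing", "feature_type")
    return res


def interaction_coefficient(result: ModelResult,
                            must_contain: tuple[str, ...] = (":",)
                            ) -> tuple[str, float]:
    """Name and estimate of the (first) interaction coefficient."""
    for name in result.params.index:
        if all(tok in name for tok in must_contain):
            return name, float(result.params[name])
    raise KeyError(f"no coefficient containing {must_contain}")


# ---------------------------------------------------------------------------
# Estimated marginal means with Tukey-adjusted pairwise comparisons
# ---------------------------------------------------------------------------

def _design_row(params_index, frame: pd.DataFrame, cell: dict) -> np.ndarray:
    """Row of the fixed-effects design matrix for one factor cell with all
    numeric covariates at their frame means (the emmeans reference grid)."""
    row = np.zeros(len(params_index))
    numeric_means = {c: frame[c].mean()
                     for c in frame.columns
                     if pd.api.types.is_numeric_dtype(frame[c])}
    for j, name in enumerate(params_index):
        row[j] = _term_value(name, cell, numeric_means)
    return row


def _term_value(name: str, cell: dict, numeric_means: dict) -> float:
    if name == "Intercept":
        return 1.0
    parts = name.split(":")
    val = 1.0
    for p in parts:
        if "[" in p:  # categorical level, e.g. cueing[T.cued]
            fac = p.split("[")[0]
            level = p.split("T.")[1].rstrip("]")
            lv = str(cell.get(fac, ""))
            val *= 1.0 if lv == level else 0.0
        else:
            val *= float(numeric_means.get(p, 0.0))
    return val


def estimated_marginal_means(result: ModelResult, frame: pd.DataFrame,
                             *factors: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cell means of the factor grid at mean covariates, plus all pairwise
    comparisons with Tukey (studentized-range) adjusted p-values.

    Degrees of freedom use the large-sample value (n_obs - n_fixed_params),
    a documented approximation to the Kenward-Roger df of the reference
    R tooling.
    """
    levels = [list(frame[f].cat.categories) if hasattr(frame[f], "cat")
              else sorted(frame[f].unique()) for f in factors]
    cells = [dict(zip(factors, combo)) for combo in itertools.product(*levels)]
    idx = result.params.index
    V = result.cov.to_numpy()
    beta = result.params.to_numpy()
    L = np.stack([_design_row(idx, frame, c) for c in cells])
    est = L @ beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", L, V, L))
    emm = pd.DataFrame({**{f: [c[f] for c in cells] for f in factors},
                        "emmean": est, "se": se})
    k = len(cells)
    df_resid = max(result.n_obs - len(beta), 2)
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        d = est[i] - est[j]
        l = L[i] - L[j]
        sed = float(np.sqrt(l @ V @ l))
        q = abs(d) / sed * np.sqrt(2.0)
        p = float(stats.studentized_range.sf(q, k, df_resid))
        rows.append({"lhs": _cell_name(cells[i]), "rhs": _cell_name(cells[j]),
                     "estimate": d, "se": sed, "t": d / sed, "p_tukey": p})
    return emm, pd.DataFrame(rows)


def _cell_name(cell: dict) -> str:
    return ",".join(f"{v}" for v in cell.values())


# ---------------------------------------------------------------------------
# Within-object tradeoff slopes
# ---------------------------------------------------------------------------

@dataclass
class SlopeResult:
    slopes: pd.Series          # per subject
    mean: float
    t: float
    p: float
    n: int
    excluded: list[str]


def tradeoff_slopes(dataset: pd.DataFrame, which: str = "post") -> SlopeResult:
    """Per-subject OLS slope predicting an object's shared-feature accuracy
    from its unique-feature accuracy, with a one-sample t test of the mean
    slope against zero.

    Uses only studied non-prototype objects (those contributing both feature
    types). Subjects with fewer than two such objects, or with no variance in
    unique accuracy, are excluded.
    """
    col = {"pre": "prenap_accuracy", "post": "postnap_accuracy"}[which]
    df = dataset[~dataset["is_novel"]]
    wide = df.pivot_table(index=["subject", "item"], columns="feature_type",
                          values=col)
    wide = wide.dropna(subset=["shared", "unique"]) if "unique" in wide else wide.iloc[0:0]
    slopes = {}
    excluded = []
    for subj, grp in wide.groupby(level="subject"):
        if len(grp) < 2 or np.isclose(grp["unique"].var(), 0.0):
            excluded.append(str(subj))
            continue
        b = np.polyfit(grp["unique"].to_numpy(), grp["shared"].to_numpy(), 1)[0]
        slopes[str(subj)] = float(b)
    s = pd.Series(slopes, dtype=float)
    if len(s) < 2:
        raise DegenerateDesignError("fewer than 2 subjects with defined slopes")
    t, p = stats.ttest_1samp(s, 0.0)
    return SlopeResult(slopes=s, mean=float(s.mean()), t=float(t),
                       p=float(p), n=len(s), excluded=excluded)


def paired_slope_change(dataset: pd.DataFrame) -> dict:
    """Pre- vs post-nap change in the tradeoff slope (paired t over the
    subjects contributing to both tests)."""
    pre = tradeoff_slopes(dataset, "pre").slopes
    post = tradeoff_slopes(dataset, "post").slopes
    common = pre.index.intersection(post.index)
    diff = post[common] - pre[common]
    t, p = stats.ttest_rel(post[common], pre[common])
    return {"change": float(diff.mean()), "t": float(t), "p": float(p),
            "n": len(common)}
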