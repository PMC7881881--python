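"""Inferential stages: window tables, pooled correlations, 2x2 factorial
ANOVA with partial eta squared, and the mixture-count robustness sweep.

Pooled correlations treat each three-minute window as an independent
observation (each scatter dot is one window); a subject-level aggregation
mode is available but is not the default.  The 2x2 ANOVA uses Type-III sums
of squares with sum-to-zero contrasts, which is well defined for unbalanced
cells (e.g. 11 female vs 27 male subjects).  Partial eta squared
``SS_effect / (SS_effect + SS_error)`` is reported per effect, with
0.01 / 0.06 / 0.14 conventionally read as small / medium / large.
Significance threshold 0.05; no multiple-testing correction by default, with
Holm available behind a flag.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as _st

__all__ = [
    "build_window_table",
    "pooled_correlation",
    "anova_2x2",
    "robustness_sweep",
    "holm_correction",
]

logger = logging.getLogger(__name__)

METRIC_COLUMNS = [
    "fixation_duration",
    "saccade_amplitude",
    "spatial_entropy",
    "transition_entropy",
    "delta_hr",
    "delta_rmssd",
    "delta_scl",
]
KEY_COLUMNS = ["subject", "scene", "modality", "gender", "window_index"]


def build_window_table(frames) -> pd.DataFrame:
    """Join per-stage metric tables into one row per subject x scene x
    modality x window.

    ``frames`` is an iterable of DataFrames each carrying the key columns
    (subject, scene, modality, gender, window_index) plus metric columns.
    Rows with any missing (NaN) metric are excluded from downstream tests;
    the exclusion count is logged.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("no tables to join")
    out = frames[0]
    for f in frames[1:]:
        keys = [k for k in KEY_COLUMNS if k in out.columns and k in f.columns]
        out = out.merge(f, on=keys, how="outer")
    metric_cols = [c for c in METRIC_COLUMNS if c in out.columns]
    flagged = out[metric_cols].isna().any(axis=1)
    if flagged.any():
        logger.info("excluding %d rows with flagged/missing metrics", flagged.sum())
    return out[~flagged].reset_index(drop=True)


def pooled_correlation(
    x,
    y,
    by_subject: pd.Series | None = None,
):
    """Pearson correlation over pooled windows.

    Returns ``(r, p, n)`` with a two-sided p-value from the t distribution
    with n-2 degrees of freedom.  If ``by_subject`` is given, observations
    are first averaged within subject (the non-default aggregation mode).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if by_subject is not None:
        d = pd.DataFrame({"x": x, "y": y, "s": np.asarray(by_subject)})
        agg = d.groupby("s").mean()
        x, y = agg["x"].to_numpy(), agg["y"].to_numpy()
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    r, p = _st.pearsonr(x, y)
    return float(r), float(p), n


def anova_2x2(
    values,
    factor_a,
    factor_b,
    names: tuple = ("A", "B"),
) -> pd.DataFrame:
    """2x2 factorial ANOVA with Type-III sums of squares (sum-to-zero
    contrasts) and partial eta squared per effect.

    Returns a DataFrame indexed by effect (A, B, A:B) with columns
    ``F``, ``p``, ``partial_eta_sq``, ``SS``, ``df``.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame(
        {
            "y": np.asarray(values, dtype=float),
            "fa": np.asarray(factor_a),
            "fb": np.asarray(factor_b),
        }
    ).dropna()
    for col in ("fa", "fb"):
        levels = df[col].unique()
        if len(levels) != 2:
            raise ValueError(f"factor {col} must have exactly 2 levels, got {levels}")
    cells = df.groupby(["fa", "fb"]).size()
    if len(cells) < 4 or cells.min() < 2:
        raise ValueError("every cell needs at least 2 observations")

    model = smf.ols("y ~ C(fa, Sum) * C(fb, Sum)", data=df).fit()
    tab = sm.stats.anova_lm(model, typ=3)
    ss_err = float(tab.loc["Residual", "sum_sq"])
    rows = {}
    labels = {
        "C(fa, Sum)": names[0],
        "C(fb, Sum)": names[1],
        "C(fa, Sum):C(fb, Sum)": f"{names[0]}:{names[1]}",
    }
    for key, label in labels.items():
        ss = float(tab.loc[key, "sum_sq"])
        rows[label] = {
            "F": float(tab.loc[key, "F"]),
            "p": float(tab.loc[key, "PR(>F)"]),
            "partial_eta_sq": ss / (ss + ss_err),
            "SS": ss,
            "df": float(tab.loc[key, "df"]),
        }
    rows["Residual"] = {
        "F": np.nan,
        "p": np.nan,
        "partial_eta_sq": np.nan,
        "SS": ss_err,
        "df": float(tab.loc["Residual", "df"]),
    }
    return pd.DataFrame(rows).T


def holm_correction(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values (optional; the default analysis
    applies no correction)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvalues, dtype=float), method="holm")[1]


def robustness_sweep(
    windows,
    base_model,
    delta_hr,
    mixture_factors=(0.75, 1.0, 1.25),
    seed: int | None = None,
):
    """Sensitivity of the entropy-ΔHR correlation to the number of emission
    mixtures.

    For each factor the per-state component counts of ``base_model`` (a
    :class:`gazephysio.model.ScanpathHMM`) are scaled, the subject-independent
    HMM is re-fit on the pooled observations, transition probabilities are
    re-estimated per window, and the pooled correlation of the per-window
    transition entropy with ``delta_hr`` is reported.

    Parameters
    ----------
    windows : list of (n_i, 2) arrays
        Per-window observation segments (fixation centroids).
    base_model : ScanpathHMM
        Unfitted model specification carrying the pooled observations and
        component counts.
    delta_hr : array-like
        One ΔHR value per window, aligned with ``windows``.

    Returns
    -------
    DataFrame indexed by factor with columns ``n_components``, ``r``, ``p``.
    """
    if len(tuple(mixture_factors)) == 0:
        raise ValueError("mixture_factors must be non-empty")
    delta_hr = np.asarray(delta_hr, dtype=float)
    if len(delta_hr) != len(windows):
        raise ValueError("delta_hr must align with windows")

    out = []
    for factor in mixture_factors:
        counts = tuple(
            max(int(round(c * factor)), 1) for c in base_model.n_components
        )
        m = base_model.with_components(counts)
        res = m.fit(seed=seed)
        ent = [res.window_entropy(w) for w in windows]
        r, p, _ = pooled_correlation(np.asarray(ent), delta_hr)
        out.append(
            {"factor": factor, "n_components": counts, "r": r, "p": p}
        )
    return pd.DataFrame(out).set_index("factor")
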