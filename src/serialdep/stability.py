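"""Within-observer test-retest stability of the serial-dependence phenotype.

Each subject's two sessions are analysed independently with the subject-
level pipeline (moving-average curve, DvM fit, two-sided permutation test,
model-free bias).  Between-session Pearson and Spearman correlations of the
amplitudes quantify stability; for the model-based amplitudes the cohort is
restricted to subjects with significant fits in both sessions, while the
model-free measure includes everyone.  The polar-angle analysis asks
whether stability is carried by the subjects with the largest biases: each
subject's (session-1, session-2) amplitude pair is summarised by
arctan(amp2 / amp1) (45 degrees = perfect test-retest equality), the cohort
is median-split on mean absolute amplitude, and the halves' polar angles
are compared with a pooled-variance two-sample t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimation import (
    estimate_with_inference,
    model_free_bias,
    model_free_permutation,
)

__all__ = [
    "per_session_estimates",
    "between_session_correlation",
    "polar_angle",
    "split_half_test",
    "StabilityReport",
    "compute_stability_report",
    "plot_stability_scatter",
]

MIN_TRIALS_PER_SESSION = 10


def per_session_estimates(
    errors: pd.DataFrame,
    n_perm: int = 1000,
    model_free_range: float = 54.0,
    mf_n_perm: int = 0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Subject-level pipeline applied to every (subject, session) cell.

    Returns one row per cell: DvM amplitude, FWHM, two-sided permutation p,
    the model-free bias (optionally with its own permutation p), and trial
    counts.  Sessions with fewer than 10 usable trials are flagged
    (``usable = False``) and carry NaN estimates.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for (subject, session), grp in errors.groupby(["subject", "session"], sort=True):
        d = grp["prev_dist_deg"].to_numpy(dtype=float)
        e = grp["error_deg"].to_numpy(dtype=float)
        row = {"subject": subject, "session": session, "n_trials": len(grp)}
        if len(grp) < MIN_TRIALS_PER_SESSION:
            row.update(
                usable=False, amplitude_deg=np.nan, fwhm_deg=np.nan,
                p_perm=np.nan, r2=np.nan, model_free_deg=np.nan, mf_p_perm=np.nan,
            )
            rows.append(row)
            continue
        fit = estimate_with_inference(
            d, e, level="subject", n_perm=n_perm, sided="two",
            seed=int(rng.integers(2**31)),
        )
        mf = model_free_bias(d, e, model_free_range)
        mf_p = (
            model_free_permutation(
                d, e, model_free_range, n_perm=mf_n_perm,
                seed=int(rng.integers(2**31)),
            )
            if mf_n_perm
            else np.nan
        )
        row.update(
            usable=True,
            amplitude_deg=fit.amplitude_deg,
            fwhm_deg=np.nan if fit.fwhm_deg is None else fit.fwhm_deg,
            p_perm=fit.p_perm,
            r2=fit.r2,
            model_free_deg=mf.bias_deg,
            mf_p_perm=mf_p,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def between_session_correlation(amp_s1, amp_s2):
    """Pearson and Spearman correlations (with two-sided p-values) between
    per-subject session-1 and session-2 amplitudes."""
    a1 = np.asarray(amp_s1, dtype=float)
    a2 = np.asarray(amp_s2, dtype=float)
    if a1.size != a2.size:
        raise ValueError("session vectors differ in length")
    if a1.size < 3:
        raise ValueError("need at least 3 subjects to correlate")
    pearson = stats.pearsonr(a1, a2)
    spearman = stats.spearmanr(a1, a2)
    return {
        "n": int(a1.size),
        "pearson_r": float(pearson.statistic),
        "pearson_p": float(pearson.pvalue),
        "spearman_rho": float(spearman.statistic),
        "spearman_p": float(spearman.pvalue),
    }


def polar_angle(amp_s1, amp_s2):
    """arctan(session-2 amplitude / session-1 amplitude), degrees.

    45 degrees means the two sessions agree exactly; NaN where both
    amplitudes are zero (the angle is undefined).  Vectorized.
    """
    a1 = np.asarray(amp_s1, dtype=float)
    a2 = np.asarray(amp_s2, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ang = np.degrees(np.arctan(np.divide(a2, a1)))
    ang = np.where(a1 == 0.0, np.sign(a2) * 90.0, ang)
    ang = np.where((a1 == 0.0) & (a2 == 0.0), np.nan, ang)
    return ang if ang.ndim else float(ang)


def split_half_test(polar_angles, mean_abs_amplitudes):
    """Median split on mean absolute amplitude; pooled-variance two-sample
    t-test (bottom minus top half) of the polar angles, with Cohen's d.

    Subjects exactly at the median join the bottom half.  Requires at least
    4 subjects with defined polar angles.
    """
    ang = np.asarray(polar_angles, dtype=float)
    amp = np.asarray(mean_abs_amplitudes, dtype=float)
    ok = ~np.isnan(ang)
    ang, amp = ang[ok], amp[ok]
    if ang.size < 4:
        raise ValueError("need at least 4 subjects for the split-half test")
    med = float(np.median(amp))
    bottom = amp <= med
    top = ~bottom
    if top.sum() == 0:  # all amplitudes identical
        bottom = np.arange(ang.size) < ang.size // 2
        top = ~bottom
    t, p = stats.ttest_ind(ang[bottom], ang[top], equal_var=True)
    n1, n2 = int(bottom.sum()), int(top.sum())
    s_pooled = math.sqrt(
        (
            (n1 - 1) * np.var(ang[bottom], ddof=1)
            + (n2 - 1) * np.var(ang[top], ddof=1)
        )
        / (n1 + n2 - 2)
    )
    d = float((ang[bottom].mean() - ang[top].mean()) / s_pooled) if s_pooled > 0 else 0.0
    return {
        "t": float(t),
        "p": float(p),
        "df": n1 + n2 - 2,
        "cohens_d": d,
        "mean_bottom": float(ang[bottom].mean()),
        "mean_top": float(ang[top].mean()),
        "n_bottom": n1,
        "n_top": n2,
    }


@dataclass
class StabilityReport:
    """Cohort-level test-retest report."""

    per_subject: pd.DataFrame
    model_based: dict = field(default_factory=dict)
    model_free: dict = field(default_factory=dict)
    split_half: dict = field(default_factory=dict)
    alpha: float = 0.05

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "model_based": self.model_based,
            "model_free": self.model_free,
            "split_half": self.split_half,
            "per_subject": self.per_subject.to_dict(orient="records"),
        }


def compute_stability_report(
    session_estimates: pd.DataFrame, alpha: float = 0.05
) -> StabilityReport:
    """Assemble the full test-retest report from per-session estimates.

    Model-based correlations use the subjects significant (p < alpha) in
    both sessions; FWHM correlations additionally require a defined FWHM in
    both sessions; model-free correlations use all usable subjects.  The
    polar-angle split-half test runs on the model-based subset.
    """
    wide = session_estimates[session_estimates["usable"]].pivot(
        index="subject", columns="session",
        values=["amplitude_deg", "fwhm_deg", "p_perm", "model_free_deg"],
    )
    a1 = wide[("amplitude_deg", 1)]
    a2 = wide[("amplitude_deg", 2)]
    sig = (wide[("p_perm", 1)] < alpha) & (wide[("p_perm", 2)] < alpha)

    per_subject = pd.DataFrame(
        {
            "subject": wide.index,
            "amplitude_s1": a1.to_numpy(),
            "amplitude_s2": a2.to_numpy(),
            "fwhm_s1": wide[("fwhm_deg", 1)].to_numpy(),
            "fwhm_s2": wide[("fwhm_deg", 2)].to_numpy(),
            "p_s1": wide[("p_perm", 1)].to_numpy(),
            "p_s2": wide[("p_perm", 2)].to_numpy(),
            "model_free_s1": wide[("model_free_deg", 1)].to_numpy(),
            "model_free_s2": wide[("model_free_deg", 2)].to_numpy(),
            "both_significant": sig.to_numpy(),
        }
    ).reset_index(drop=True)
    per_subject["polar_angle"] = polar_angle(
        per_subject["amplitude_s1"], per_subject["amplitude_s2"]
    )

    report = StabilityReport(per_subject=per_subject, alpha=alpha)
    sub = per_subject[per_subject["both_significant"]]
    if len(sub) >= 3:
        report.model_based = between_session_correlation(
            sub["amplitude_s1"], sub["amplitude_s2"]
        )
        fw = sub.dropna(subset=["fwhm_s1", "fwhm_s2"])
        if len(fw) >= 3:
            report.model_based["fwhm"] = between_session_correlation(
                fw["fwhm_s1"], fw["fwhm_s2"]
            )
    if len(per_subject) >= 3:
        report.model_free = between_session_correlation(
            per_subject["model_free_s1"], per_subject["model_free_s2"]
        )
    if len(sub) >= 4:
        mean_abs = (sub["amplitude_s1"].abs() + sub["amplitude_s2"].abs()) / 2.0
        report.split_half = split_half_test(sub["polar_angle"], mean_abs)
    return report


def plot_stability_scatter(report: StabilityReport, path):
    """Session-1 vs session-2 amplitude scatter with the identity line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    df = report.per_subject
    sig = df["both_significant"].to_numpy(dtype=bool)
    ax.scatter(
        df.loc[sig, "amplitude_s1"], df.loc[sig, "amplitude_s2"],
        c="crimson", label="significant both sessions",
    )
    ax.scatter(
        df.loc[~sig, "amplitude_s1"], df.loc[~sig, "amplitude_s2"],
        c="lightgray", label="other subjects",
    )
    lim = max(1.0, df[["amplitude_s1", "amplitude_s2"]].abs().to_numpy().max()) * 1.1
    ax.plot([-lim, lim], [-lim, lim], ls=":", c="gray")
    ax.set_xlim(-lim, lim)
    ax.set_ylim(-lim, lim)
    ax.set_xlabel("session 1 amplitude (deg)")
    ax.set_ylabel("session 2 amplitude (deg)")
    if report.model_based:
        ax.set_title(f"test-retest r = {report.model_based['pearson_r']:.3f}")
    ax.legend(fontsize=7, loc="upper left")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
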