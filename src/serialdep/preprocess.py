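"""Trial selection, lapse removal, and residualization.

The serial-dependence analysis uses only *no-switch, no-rotation* trials:
adjustment-mode no-rotation trials that received a response and whose
immediately preceding trial (in presentation order, within the same block)
was also a responded adjustment no-rotation trial.  Response errors more
than three circular SDs from the subject-and-session mean are treated as
attentional lapses and removed, and the session-wide mean directional
error (the subject's global bias) is subtracted so that only residual,
history-dependent error enters the estimators.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import design as dsg
from .circular import circ_dist, circ_mean, circ_sd, wrap_signed

ERROR_COLUMNS = [
    "subject",
    "session",
    "block",
    "trial",
    "error_deg",
    "prev_dist_deg",
    "next_dist_deg",
    "included",
]

__all__ = [
    "select_trials",
    "remove_lapses",
    "residualize",
    "summarize_performance",
    "ERROR_COLUMNS",
]


def select_trials(table: pd.DataFrame) -> pd.DataFrame:
    """Extract the analysis set (no-switch, no-rotation trials) as an
    error table.

    For each qualifying trial the table records the signed response error
    (response minus stimulus), the signed distance to the previous
    stimulus (previous minus current, the serial-dependence axis), and the
    signed distance to the upcoming stimulus within the same block (for
    the temporal-control analysis; NaN at block ends).

    Raises ``ValueError`` if the table lacks required columns or is not in
    presentation order within blocks.
    """
    required = {
        "subject",
        "session",
        "block",
        "trial",
        "task",
        "response_mode",
        "stimulus_deg",
        "response_deg",
    }
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")

    keys = ["subject", "session", "block"]
    trial_steps = table.groupby(keys, sort=False)["trial"].diff().dropna()
    if (trial_steps <= 0).any():
        raise ValueError("trial table is not in presentation order within blocks")

    stim = table["stimulus_deg"].to_numpy(dtype=float)
    resp = table["response_deg"].to_numpy(dtype=float)
    responded = (table["response_mode"].to_numpy() == dsg.MODE_ADJUST) & ~np.isnan(resp)
    qualifies_self = (table["task"].to_numpy() == dsg.TASK_NO_ROTATION) & responded

    grouped = table.assign(_q=qualifies_self).groupby(keys, sort=False)
    prev_q = grouped["_q"].shift(1, fill_value=False).to_numpy(dtype=bool)
    prev_stim = grouped["stimulus_deg"].shift(1).to_numpy(dtype=float)
    next_stim = grouped["stimulus_deg"].shift(-1).to_numpy(dtype=float)

    keep = qualifies_self & prev_q & ~np.isnan(prev_stim)
    out = table.loc[keep, ["subject", "session", "block", "trial"]].copy()
    out["error_deg"] = wrap_signed(resp[keep] - stim[keep])
    out["prev_dist_deg"] = wrap_signed(prev_stim[keep] - stim[keep])
    ns = next_stim[keep]
    nd = np.full(len(out), np.nan)
    ok = ~np.isnan(ns)
    nd[ok] = wrap_signed(ns[ok] - stim[keep][ok])
    out["next_dist_deg"] = nd
    out["included"] = True
    return out.reset_index(drop=True)[ERROR_COLUMNS]


def remove_lapses(errors: pd.DataFrame):
    """Drop lapse trials: error further than 3 circular SDs from the
    subject-and-session circular mean error.

    A single, non-iterated pass using the doubled-angle circular metric.
    Returns ``(filtered, removal_log)`` where the log counts removed trials
    per (subject, session).  Raises on groups with fewer than 2 trials.
    """
    if errors.empty:
        raise ValueError("cannot filter an empty error table")
    kept, log_rows = [], []
    for (subject, session), grp in errors.groupby(["subject", "session"], sort=False):
        if len(grp) < 2:
            raise ValueError(
                f"subject {subject} session {session}: need >=2 trials to filter"
            )
        e = grp["error_deg"].to_numpy(dtype=float)
        m, sd = circ_mean(e), circ_sd(e)
        dev = np.abs(circ_dist(e, m))
        keep = dev <= 3.0 * sd
        kept.append(grp.loc[keep])
        log_rows.append(
            {
                "subject": subject,
                "session": session,
                "n_in": len(grp),
                "n_removed": int((~keep).sum()),
                "circ_mean": m,
                "circ_sd": sd,
            }
        )
    return (
        pd.concat(kept, ignore_index=True),
        pd.DataFrame(log_rows),
    )


def residualize(errors: pd.DataFrame) -> pd.DataFrame:
    """Subtract each subject-and-session circular mean error (global bias)
    from the individual errors; distances are untouched."""
    out = errors.copy()
    for _, idx in out.groupby(["subject", "session"], sort=False).groups.items():
        e = out.loc[idx, "error_deg"].to_numpy(dtype=float)
        out.loc[idx, "error_deg"] = circ_dist(e, circ_mean(e))
    return out


def summarize_performance(errors: pd.DataFrame):
    """Per-subject mean absolute error and dispersion (circular SD), with
    cohort mean +/- SEM of each."""
    if errors.empty:
        raise ValueError("empty error table")
    rows = []
    for subject, grp in errors.groupby("subject", sort=False):
        e = grp["error_deg"].to_numpy(dtype=float)
        rows.append(
            {
                "subject": subject,
                "mean_abs_error": float(np.mean(np.abs(e))),
                "dispersion": circ_sd(e),
                "n_trials": len(grp),
            }
        )
    per_subject = pd.DataFrame(rows)
    n = len(per_subject)
    summary = {}
    for col in ("mean_abs_error", "dispersion"):
        v = per_subject[col].to_numpy()
        summary[col] = float(np.mean(v))
        summary[f"{col}_sem"] = float(np.std(v, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return per_subject, summary
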