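"""Signal-detection analysis of go/no-go sessions and the
statistics-neural-behavior linking table.

Behavioral discriminability is the classic equal-variance d' =
Z(hit rate) - Z(false-alarm rate); perfect rates are adjusted by the
1/(2N) rule before the inverse-normal transform.  The linking table joins
per-family behavioral d', decoder accuracy and stimulus-statistics distance
and reports Spearman rank correlations with bootstrap confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

__all__ = [
    "SessionCounts",
    "session_counts",
    "session_dprime",
    "training_criterion",
    "build_link_table",
]


@dataclass(frozen=True)
class SessionCounts:
    hits: int
    misses: int
    false_alarms: int
    correct_rejects: int

    @property
    def n_go(self) -> int:
        return self.hits + self.misses

    @property
    def n_nogo(self) -> int:
        return self.false_alarms + self.correct_rejects


def session_counts(log: pd.DataFrame) -> SessionCounts:
    """Tally hit/miss/false-alarm/correct-reject from a trial-level log.

    Expects ``stim_class`` in {'go', 'nogo'} and boolean ``response``; rows
    flagged ``aborted == True`` (if the column exists) are excluded.
    """
    df = log
    if "aborted" in df.columns:
        df = df[~df.aborted.astype(bool)]
    go = df.stim_class == "go"
    resp = df.response.astype(bool)
    return SessionCounts(
        hits=int((go & resp).sum()),
        misses=int((go & ~resp).sum()),
        false_alarms=int((~go & resp).sum()),
        correct_rejects=int((~go & ~resp).sum()),
    )


def _adjusted_rate(k: int, n: int) -> tuple[float, bool]:
    """Proportion with the 1/(2N) adjustment for perfect rates."""
    r = k / n
    if r == 0.0:
        return 1.0 / (2 * n), True
    if r == 1.0:
        return 1.0 - 1.0 / (2 * n), True
    return r, False


def session_dprime(log: pd.DataFrame | SessionCounts, return_rates: bool = False):
    """d' = Z(hit rate) - Z(false-alarm rate).

    Accepts a trial-level log or precomputed :class:`SessionCounts`.  Rates of
    exactly 0 or 1 are moved inward by 1/(2N) (logged via warning) before the
    inverse-normal transform.
    """
    c = log if isinstance(log, SessionCounts) else session_counts(log)
    if c.n_go == 0 or c.n_nogo == 0:
        raise ValueError("need at least one go and one no-go trial")
    hit, adj_h = _adjusted_rate(c.hits, c.n_go)
    fa, adj_f = _adjusted_rate(c.false_alarms, c.n_nogo)
    if adj_h or adj_f:
        warnings.warn("extreme rate adjusted by the 1/(2N) rule")
    d = float(sp_stats.norm.ppf(hit) - sp_stats.norm.ppf(fa))
    if return_rates:
        return d, dict(hit_rate=hit, fa_rate=fa)
    return d


def training_criterion(
    session_dprimes, threshold: float = 1.0, run_length: int = 10
) -> int | None:
    """Index of the session completing the first run of ``run_length``
    consecutive sessions with d' > ``threshold``; None if never reached."""
    run = 0
    for i, d in enumerate(session_dprimes):
        run = run + 1 if d > threshold else 0
        if run >= run_length:
            return i
    return None


def build_link_table(
    behavior_logs: pd.DataFrame,
    decoder_accuracy: dict,
    stat_distances: dict,
    n_boot: int = 1000,
    rng_seed: int = 0,
):
    """Join behavioral d', decoder accuracy and statistics distance per family.

    ``behavior_logs`` is a trial-level log with ``family`` and ``session``
    columns; ``decoder_accuracy`` and ``stat_distances`` map family -> value
    (decoder_accuracy values may be dicts area -> accuracy).  Returns
    ``(table, correlations)`` where correlations holds Spearman rho of d' and
    of each accuracy column against the distance, with bootstrap CIs over
    sessions (NaN rho when a variable is constant).
    """
    rng = np.random.default_rng(rng_seed)
    fams = sorted(stat_distances)
    per_session = {}
    rows = []
    for fam in fams:
        sub = behavior_logs[behavior_logs.family == fam]
        ds = [session_dprime(g) for _, g in sub.groupby("session")]
        per_session[fam] = np.array(ds)
        acc = decoder_accuracy[fam]
        row = dict(
            family=fam,
            behavior_dprime=float(np.mean(ds)),
            behavior_dprime_se=float(np.std(ds, ddof=1) / np.sqrt(len(ds))) if len(ds) > 1 else np.nan,
            stat_distance=float(stat_distances[fam]),
        )
        if isinstance(acc, dict):
            for area, v in acc.items():
                row[f"decoder_accuracy_{area}"] = float(v)
        else:
            row["decoder_accuracy"] = float(acc)
        rows.append(row)
    table = pd.DataFrame(rows)

    dist = table.stat_distance.to_numpy()
    correlations = {}

    def _spearman(x, y):
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return np.nan
        return float(sp_stats.spearmanr(x, y).statistic)

    rho = _spearman(dist, table.behavior_dprime.to_numpy())
    boot = []
    if not np.isnan(rho):
        for _ in range(n_boot):
            d_mean = [
                np.mean(per_session[f][rng.integers(0, len(per_session[f]), len(per_session[f]))])
                for f in fams
            ]
            boot.append(_spearman(dist, np.array(d_mean)))
        boot = np.array(boot)
        ci = (float(np.nanpercentile(boot, 2.5)), float(np.nanpercentile(boot, 97.5)))
    else:
        ci = (np.nan, np.nan)
    correlations["behavior_dprime"] = dict(spearman_rho=rho, ci95=ci)
    for col in table.columns:
        if col.startswith("decoder_accuracy"):
            correlations[col] = dict(
                spearman_rho=_spearman(dist, table[col].to_numpy())
            )
    return table, correlations
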