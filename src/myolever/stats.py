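"""Replicate-level statistics: RMSD summary tables, RMSF differencing, t-tests.

Replicates — not frames — are the statistical units throughout: each
replicate simulation contributes one time-averaged observation per quantity,
and conditions (apo vs holo) are compared with a pooled-variance two-tailed
Student's t-test on those observations.  With three replicates per condition
this matches the classic small-n design.  No multiple-testing correction is
applied by default (raw p < α counts are reported); an optional
Benjamini-Hochberg switch is available for the residue map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .alignment import RMSFProfile

__all__ = [
    "students_t_two_tailed",
    "rmsd_summary_table",
    "rmsf_difference_map",
]


def students_t_two_tailed(group_a, group_b) -> tuple[float, float]:
    """Pooled-variance Student's t with df = nA + nB − 2; two-tailed p.

    Degenerate convention (documented): zero pooled variance with equal means
    gives p = 1; zero pooled variance with unequal means gives p = 0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
    if pooled == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float("inf"), 0.0
    import warnings

    with warnings.catch_warnings():
        # near-identical groups trigger a harmless precision warning
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def rmsd_summary_table(
    apo: dict[str, dict[str, np.ndarray]],
    holo: dict[str, dict[str, np.ndarray]],
) -> pd.DataFrame:
    """Condense per-replicate RMSD series into a per-mask-mode summary table.

    Parameters
    ----------
    apo, holo
        ``{mask mode: {replicate label: per-frame RMSD series (Å)}}``.  The
        two conditions must share the same mask modes and have at least two
        replicates each.

    Returns a table with one row per mask mode: per-replicate time averages,
    condition averages, and the two-tailed Student's t p-value computed on
    the replicate averages.
    """
    if set(apo) != set(holo):
        raise ValueError("apo and holo must provide the same mask modes")
    rows = []
    for mode in apo:
        if len(apo[mode]) < 2 or len(holo[mode]) < 2:
            raise ValueError(f"mask mode '{mode}' needs >= 2 replicates per condition")
        a_means = {rep: float(np.mean(series)) for rep, series in apo[mode].items()}
        h_means = {rep: float(np.mean(series)) for rep, series in holo[mode].items()}
        _, p = students_t_two_tailed(list(a_means.values()), list(h_means.values()))
        row = {"mode": mode}
        row.update({f"apo_{rep}": v for rep, v in a_means.items()})
        row["apo_avg"] = float(np.mean(list(a_means.values())))
        row.update({f"holo_{rep}": v for rep, v in h_means.items()})
        row["holo_avg"] = float(np.mean(list(h_means.values())))
        row["p_value"] = p
        rows.append(row)
    return pd.DataFrame(rows).set_index("mode")


@dataclass
class ResidueDifferenceMap:
    """Per-residue apo-vs-holo RMSF comparison (positive Δ = apo more mobile)."""

    table: pd.DataFrame  # columns: chain, resid, rmsf_apo, rmsf_holo, delta, p_value, significant

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())


def rmsf_difference_map(
    apo: list[RMSFProfile],
    holo: list[RMSFProfile],
    alpha: float = 0.05,
    bh_correction: bool = False,
) -> ResidueDifferenceMap:
    """Residue-wise ΔRMSF (apo − holo) with per-residue Student's t-tests.

    Each replicate's per-residue RMSF is one observation; residues are
    flagged significant at p < ``alpha`` (optionally Benjamini-Hochberg
    adjusted when ``bh_correction`` is set).
    """
    if len(apo) < 2 or len(holo) < 2:
        raise ValueError("need at least 2 replicates per condition")

    def _keys(prof: RMSFProfile):
        return list(zip(prof.chain, prof.resid))

    ref = _keys(apo[0])
    for prof in apo[1:] + holo:
        if _keys(prof) != ref:
            sym = set(_keys(prof)) ^ set(ref)
            raise ValueError(f"residue sets differ between profiles: {sorted(sym)[:10]}")
    a = np.stack([p.rmsf for p in apo])     # (n_rep, n_res)
    h = np.stack([p.rmsf for p in holo])
    rows = []
    for j, (chain, resid) in enumerate(ref):
        _, p = students_t_two_tailed(a[:, j], h[:, j])
        rows.append(
            {
                "chain": chain,
                "resid": resid,
                "rmsf_apo": float(a[:, j].mean()),
                "rmsf_holo": float(h[:, j].mean()),
                "delta": float(a[:, j].mean() - h[:, j].mean()),
                "p_value": p,
            }
        )
    table = pd.DataFrame(rows)
    if bh_correction:
        p = table["p_value"].to_numpy()
        order = np.argsort(p)
        m = len(p)
        adj = np.empty(m)
        running = 1.0
        for rank in range(m - 1, -1, -1):
            i = order[rank]
            running = min(running, p[i] * m / (rank + 1))
            adj[i] = running
        table["p_adjusted"] = adj
        table["significant"] = table["p_adjusted"] < alpha
    else:
        table["significant"] = table["p_value"] < alpha
    return ResidueDifferenceMap(table=table)
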