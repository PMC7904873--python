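"""Population-level contingency statistics and summary reports.

The headline population contrasts are (a) the proportion of LFP recording
sites with a significant evoked response in sleep vs wakefulness, tested
with Fisher's exact test on the 2x2 site table, and (b) the per-animal
breakdown of unit response categories with exact tests on the excess of
exclusively-sleep-responsive cells.

The exclusivity contrast admits two natural 2x2 constructions (an unpaired
table of exclusive counts against totals, and an exact binomial on the
discordant pair of a paired table); both are computed and labelled, and
neither is asserted as canonical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lfp_response import RotResult
from .spike_response import CellCategory, tabulate_cells


@dataclass
class SiteSummary:
    n_sites: int
    n_responsive_sleep: int
    n_responsive_wake: int
    table: list[list[int]]
    fisher_p_one_sided: float   # directional: sleep proportion higher
    fisher_p_two_sided: float
    per_site: dict[str, dict[str, bool]]


def fisher_exact_2x2(
    table, alternative: str = "two-sided"
) -> float:
    """Fisher's exact test p-value for a 2x2 table of counts.

    ``two-sided`` follows the probability-mass convention (sum of
    hypergeometric probabilities of tables at most as likely as the one
    observed); ``greater``/``less`` give the one-sided tails.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer) and np.any(arr != np.round(arr)):
        raise ValueError("cells must be non-negative integers")
    if arr.sum() == 0:
        raise ValueError("at least one margin must be positive")
    _, p = stats.fisher_exact(arr.astype(int), alternative=alternative)
    return float(p)


def site_proportion_report(
    results: dict[str, dict[str, RotResult | bool]],
    alpha: float = 0.05,
) -> SiteSummary:
    """Build the state x responsive/non-responsive site table and test it.

    ``results`` maps site label -> {"SWS": verdict, "WAKE": verdict}; a
    verdict is a :class:`RotResult` (gated at ``alpha``) or a plain bool.
    The one-sided (sleep proportion greater) Fisher p is the headline value;
    the two-sided p is reported alongside.
    """
    per_site: dict[str, dict[str, bool]] = {}
    for site, by_state in results.items():
        missing = [s for s in ("SWS", "WAKE") if s not in by_state]
        if missing:
            raise ValueError(f"site {site!r} missing state(s) {missing}")
        per_site[site] = {
            state: (v.responsive(alpha) if isinstance(v, RotResult) else bool(v))
            for state, v in by_state.items()
        }
    n = len(per_site)
    n_sleep = sum(v["SWS"] for v in per_site.values())
    n_wake = sum(v["WAKE"] for v in per_site.values())
    table = [[n_sleep, n - n_sleep], [n_wake, n - n_wake]]
    return SiteSummary(
        n_sites=n,
        n_responsive_sleep=n_sleep,
        n_responsive_wake=n_wake,
        table=table,
        fisher_p_one_sided=fisher_exact_2x2(table, "greater"),
        fisher_p_two_sided=fisher_exact_2x2(table, "two-sided"),
        per_site=per_site,
    )


def cell_report_from_counts(
    counts: dict[str, tuple[int, int, int, int, int, int]],
) -> pd.DataFrame:
    """Population report from per-group count tuples.

    Each tuple is ``(recorded, responded, sleep_only, wake_only,
    both_opposite, both_same)``.  The responder partition
    ``responded == sleep_only + wake_only + both_opposite + both_same`` is
    enforced.  Appended rows give the two candidate exact tests on the
    sleep-exclusivity excess, each labelled with its construction.
    """
    rows = {}
    for group, (rec, resp, s_only, w_only, opp, same) in counts.items():
        if s_only + w_only + opp + same != resp:
            raise ValueError(
                f"group {group!r}: categories sum to {s_only + w_only + opp + same},"
                f" expected {resp} responders"
            )
        if resp > rec:
            raise ValueError(f"group {group!r}: responders exceed recorded")
        p_unpaired = fisher_exact_2x2(
            [[s_only, rec - s_only], [w_only, rec - w_only]], "two-sided"
        )
        n_disc = s_only + w_only
        p_binom = (
            stats.binomtest(min(s_only, w_only), n_disc, 0.5).pvalue if n_disc else 1.0
        )
        rows[group] = {
            "recorded": rec,
            "responded": resp,
            "sleep_only": s_only,
            "wake_only": w_only,
            "both_opposite": opp,
            "both_same": same,
            "none": rec - resp,
            "p_exclusive_unpaired_fisher": p_unpaired,
            "p_exclusive_exact_binomial": float(p_binom),
        }
    return pd.DataFrame(rows)


def cell_report(categories: dict[str, list[CellCategory]]) -> pd.DataFrame:
    """Population report from per-group classified units (see above)."""
    tab = tabulate_cells(categories)
    counts = {
        g: (
            int(tab[g]["recorded"]),
            int(tab[g]["responded"]),
            int(tab[g]["sleep_only"]),
            int(tab[g]["wake_only"]),
            int(tab[g]["both_opposite"]),
            int(tab[g]["both_same"]),
        )
        for g in tab.columns
    }
    return cell_report_from_counts(counts)
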