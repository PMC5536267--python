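"""Indifference-point extraction from titration choice sequences.

The indifference point (IP) of one EDQ page is the last effortless amount the
participant chose before switching preference to the effortful alternative:
it approximates the subjective value (SV) of the effortful payoff.  Two limit
conventions close the rule: choosing the effortful option already in the top
row (where both amounts are equal) means no discounting, SV = A; never
switching means the reward is fully discounted, SV = 0.
"""

from __future__ import annotations

import logging

import pandas as pd

from .design import DesignSpec, TitrationLadder, build_ladder

__all__ = [
    "AmbiguousSequenceError",
    "MissingCellError",
    "extract_ip",
    "extract_ips",
    "apply_exclusions",
    "group_median_ips",
]

log = logging.getLogger(__name__)

MEDIAN_UNIT = "MEDIAN"


class AmbiguousSequenceError(ValueError):
    """Choice sequence with more than one preference switch."""


class MissingCellError(ValueError):
    """A design cell has no observations."""


def extract_ip(choices: pd.DataFrame, ladder: TitrationLadder) -> float:
    """Extract the indifference point of one participant x condition.

    ``choices`` holds the rows of a single page (columns ``row_index`` and
    ``choice``); the sequence may stop at the switch row, as the EDQ
    procedure prescribes, or continue with effortful choices to the bottom.
    """
    seq = choices.sort_values("row_index")
    tokens = seq["choice"].tolist()
    first_effortful = None
    for i, token in enumerate(tokens):
        if token == "effortful":
            first_effortful = i
            break
    if first_effortful is not None:
        if "effortless" in tokens[first_effortful:]:
            raise AmbiguousSequenceError(
                "choice sequence switches more than once")
        if first_effortful == 0:
            return float(ladder.amount)  # no discounting
        return float(seq["effortless_value"].iloc[first_effortful - 1])
    # Never switched: requires the sequence to reach the bottom (value 0) row.
    last_row = int(seq["row_index"].iloc[-1])
    if last_row != len(ladder):
        raise AmbiguousSequenceError(
            f"sequence without a switch ends at row {last_row}, "
            f"not at the ladder bottom")
    return 0.0  # full discounting


def extract_ips(choices: pd.DataFrame,
                spec: DesignSpec | None = None) -> pd.DataFrame:
    """Extract one IP per (participant, domain, amount, effort_level).

    Ambiguous (multi-switch or truncated) sequences are excluded and logged,
    not imputed: they cannot arise from the stop-at-switch procedure.
    """
    spec = spec or DesignSpec()
    ladders = {a: build_ladder(a, spec) for a in choices["amount"].unique()}
    rows = []
    for key, grp in choices.groupby(
            ["participant_id", "domain", "amount", "effort_level"], sort=False):
        participant, domain, amount, level = key
        try:
            ip = extract_ip(grp, ladders[amount])
        except AmbiguousSequenceError as exc:
            log.warning("excluding %s: %s", key, exc)
            continue
        rows.append({"participant_id": participant, "domain": domain,
                     "amount": amount, "effort_level": level, "ip": ip})
    return pd.DataFrame(rows, columns=[
        "participant_id", "domain", "amount", "effort_level", "ip"])


def apply_exclusions(ip_table: pd.DataFrame,
                     spec: DesignSpec | None = None) -> pd.DataFrame:
    """Drop the excluded first indifference points (zero-effort pages).

    Those pages oppose an immediate effortless amount to the same amount
    merely delayed by 30 minutes; they measure delay, not effort, and are
    excluded from every analysis.  Idempotent on tables without E = 0 rows.
    """
    return ip_table[ip_table["effort_level"] != 0].reset_index(drop=True)


def group_median_ips(ip_table: pd.DataFrame) -> pd.DataFrame:
    """Median IP per (domain, amount, effort_level) across participants.

    The median uses the midpoint convention for even counts.  The group table
    carries the reserved participant_id ``MEDIAN``.
    """
    if ip_table.empty:
        raise MissingCellError("cannot take group medians of an empty table")
    grouped = (ip_table
               .groupby(["domain", "amount", "effort_level"], sort=True)["ip"]
               .median().reset_index())
    counts = ip_table.groupby(["domain", "amount", "effort_level"]).size()
    if (counts < 1).any():
        raise MissingCellError(f"empty design cells: "
                               f"{counts[counts < 1].index.tolist()}")
    grouped.insert(0, "participant_id", MEDIAN_UNIT)
    return grouped
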