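"""Association between drug-combination synergy and predicted target synergy.

Drug combinations are called synergistic when their Bliss score strictly
exceeds a threshold (default 0.12). Each combination maps to the set of
target pairs drawn across its two drugs' target sets; per mapping event the
target pair's predicted synergy flag is counted into a 2x2 table, which is
tested with a Pearson chi-square and summarized by an odds ratio (add-one
corrected when any cell is zero).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from scipy import stats

from .errors import DegenerateInputError, InputError
from .io import DrugComboTable, TargetList

log = logging.getLogger(__name__)


@dataclass
class ContingencyTable:
    """2x2 counts: rows drug synergy (Y/N), columns target synergy (Y/N)."""

    a: int  # drug synergy & target synergy
    b: int  # drug synergy & target non-synergy
    c: int  # drug non-synergy & target synergy
    d: int  # drug non-synergy & target non-synergy

    def __post_init__(self):
        for name in "abcd":
            v = getattr(self, name)
            if not isinstance(v, (int,)) or v < 0:
                raise InputError(f"cell {name} must be a non-negative integer, got {v!r}")
        if self.total < 1:
            raise InputError("contingency table is empty")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def classify_drug_synergy(bliss: float, threshold: float = 0.12) -> bool:
    """Synergistic iff the Bliss score strictly exceeds the threshold."""
    if math.isnan(bliss):
        raise InputError("Bliss score is NaN")
    return bliss > threshold


def drug_pair_to_target_pairs(drug_a_targets, drug_b_targets) -> set[frozenset]:
    """All unordered cross-drug gene pairs {x, y}, x from drug A and y from
    drug B, x != y, deduplicated. Empty result logs a warning."""
    a = {str(g).upper() for g in drug_a_targets}
    b = {str(g).upper() for g in drug_b_targets}
    if not a or not b:
        raise InputError("both drugs need a non-empty target set")
    pairs = {frozenset((x, y)) for x in a for y in b if x != y}
    if not pairs:
        log.warning("drug pair maps to no distinct target pair (shared single target)")
    return pairs


def build_contingency(
    combos: DrugComboTable,
    pair_synergy: dict[frozenset, bool],
    targets: TargetList,
    threshold: float = 0.12,
) -> ContingencyTable:
    """Count (drug combination, target pair) mapping events into a 2x2 table.

    ``pair_synergy`` maps frozenset({gene1, gene2}) -> predicted synergy
    flag. A target pair mapped by several drug combinations is counted once
    per combination; pairs without a prediction are skipped (logged).
    """
    a = b = c = d = 0
    mapped_events = 0
    skipped = 0
    for drug_a, drug_b, _line, bliss in combos.records:
        ta = targets.entries.get(drug_a)
        tb = targets.entries.get(drug_b)
        if not ta or not tb:
            skipped += 1
            continue
        drug_syn = classify_drug_synergy(bliss, threshold)
        for pair in drug_pair_to_target_pairs(ta, tb):
            flag = pair_synergy.get(pair)
            if flag is None:
                continue
            mapped_events += 1
            if drug_syn and flag:
                a += 1
            elif drug_syn:
                b += 1
            elif flag:
                c += 1
            else:
                d += 1
    if skipped:
        log.warning("%d drug combinations had no target annotation", skipped)
    if mapped_events == 0:
        raise InputError("no drug combination could be mapped to a scored target pair")
    return ContingencyTable(a=a, b=b, c=c, d=d)


def chi_square_test(tab: ContingencyTable) -> tuple[float, float]:
    """Pearson chi-square without continuity correction:
    N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)); p from chi2 with 1 df."""
    a, b, c, d = tab.a, tab.b, tab.c, tab.d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise DegenerateInputError(
            f"chi-square undefined: zero margin in table ({a}, {b}, {c}, {d})"
        )
    n = tab.total
    stat = n * (a * d - b * c) ** 2 / (margins[0] * margins[1] * margins[2] * margins[3])
    p = float(stats.chi2.sf(stat, df=1))
    return float(stat), p


def odds_ratio(tab: ContingencyTable) -> float:
    """ad / bc, with an add-one correction to every cell when any cell is 0.

    Summaries report the value truncated to an integer.
    """
    a, b, c, d = tab.a, tab.b, tab.c, tab.d
    if min(a, b, c, d) == 0:
        if max(a, b, c, d) == 0:
            log.warning("degenerate all-zero table; odds ratio defaults to 1")
        a, b, c, d = a + 1, b + 1, c + 1, d + 1
    return (a * d) / (b * c)
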