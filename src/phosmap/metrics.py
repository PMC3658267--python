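"""Small evaluation-arithmetic helpers shared across the pipeline."""

from __future__ import annotations

from scipy import stats


def percent(numerator: int, denominator: int, decimals: int | None = None
            ) -> float:
    """A proportion as a percentage, rounded in reporting style.

    With ``decimals=None`` the convention is one decimal place, or two when
    the value is below 1% (so 48/6338 reports as 0.76 rather than 0.8).
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    value = 100.0 * numerator / denominator
    if decimals is None:
        decimals = 2 if value < 1.0 else 1
    return round(value, decimals)


def two_proportion_chi2(k1: int, n1: int, k2: int, n2: int):
    """Chi-square test that two proportions k1/n1 and k2/n2 differ.

    A convenience for contrasting confirmation rates between edge sets;
    returns (chi2, p_value).
    """
    table = [[k1, n1 - k1], [k2, n2 - k2]]
    chi2, p, _, _ = stats.chi2_contingency(table)
    return float(chi2), float(p)
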