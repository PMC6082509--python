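"""Independent brute-force reference implementations used only by tests."""
from typing import Optional

from aki_impact.records import ScrSeries


def brute_force_ha_onset(
    series: ScrSeries,
    ratio: float = 1.5,
    rise: float = 26.5,
    window: float = 48.0,
    horizon: float = 168.0,
) -> Optional[float]:
    """All-pairs hospital-acquired AKI check.

    A measurement at t (0 < t <= horizon) triggers if value(t)/value(0) >=
    ratio, or some earlier-or-equal measurement s with t - s <= window has
    value(t) - value(s) >= rise.  Returns the earliest triggering t.
    """
    t, v = series.times, series.values
    adm = v[0]
    hits = []
    for i in range(len(t)):
        if t[i] <= 0 or t[i] > horizon:
            continue
        if v[i] / adm >= ratio:
            hits.append(t[i])
            continue
        for j in range(len(t)):
            if t[j] <= t[i] and t[i] - t[j] <= window and v[i] - v[j] >= rise:
                hits.append(t[i])
                break
    return float(min(hits)) if hits else None


def mantel_haenszel_chi2(tables) -> float:
    """Closed-form CMH statistic (no continuity correction) over 2x2 strata."""
    num = 0.0
    var = 0.0
    for t in tables:
        n = t.a + t.b + t.c + t.d
        row1 = t.a + t.b
        row2 = t.c + t.d
        col1 = t.a + t.c
        col2 = t.b + t.d
        num += t.a - row1 * col1 / n
        var += row1 * row2 * col1 * col2 / (n * n * (n - 1))
    return num * num / var
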