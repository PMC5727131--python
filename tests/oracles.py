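"""Brute-force reference implementations of the 17 features.

Deliberately written with plain Python loops, independently of the package
internals, so they serve as oracles for the vectorized implementations.
"""

SAMPLES = 288
STEP_MIN = 5.0
STEP_H = STEP_MIN / 60.0


def mean(day):
    return sum(day) / len(day)


def sdbg(day):
    m = mean(day)
    return (sum((x - m) ** 2 for x in day) / len(day)) ** 0.5


def lage(day):
    hi = lo = day[0]
    for x in day:
        hi = max(hi, x)
        lo = min(lo, x)
    return hi - lo


def modd(day1, day2, denominator=287):
    return sum(abs(a - b) for a, b in zip(day1, day2)) / denominator


def auc_excess(day, upper, lower):
    total = 0.0
    for side in ("upper", "lower"):
        if side == "upper":
            excess = [max(x - upper, 0.0) for x in day]
        else:
            excess = [max(lower - x, 0.0) for x in day]
        closed = excess + [excess[-1]]  # day closed at midnight
        for a, b in zip(closed, closed[1:]):
            total += 0.5 * (a + b) * STEP_H
    return total


def window_means(day, meal_minutes, pre=30, post=120):
    """Per-meal (pre_mean, post_mean) using slot midpoints."""
    out = {}
    for name, t in meal_minutes.items():
        pre_vals, post_vals = [], []
        for slot, x in enumerate(day):
            mid = slot * STEP_MIN + STEP_MIN / 2
            if t - pre <= mid < t:
                pre_vals.append(x)
            elif t < mid <= t + post:
                post_vals.append(x)
        out[name] = (sum(pre_vals) / len(pre_vals), sum(post_vals) / len(post_vals))
    return out


def collapse_plateaus(day):
    runs = []
    start = 0
    for i in range(1, len(day)):
        if day[i] != day[i - 1]:
            runs.append((start, i - 1))
            start = i
    runs.append((start, len(day) - 1))
    return [day[(a + b) // 2] for a, b in runs]


def extrema(values):
    """(index, value, is_max) of strict interior extrema of a plateau-free list."""
    out = []
    for i in range(1, len(values) - 1):
        if values[i - 1] < values[i] > values[i + 1]:
            out.append((i, values[i], True))
        elif values[i - 1] > values[i] < values[i + 1]:
            out.append((i, values[i], False))
    return out


def mage(day):
    sd = sdbg(day)
    values = collapse_plateaus(list(day))
    ext = [v for _, v, _ in extrema(values)]
    if len(ext) < 3:
        return 0.0
    amps = [abs(ext[i + 1] - ext[i]) for i in range(len(ext) - 1)]
    first_valid = None
    for k in range(1, len(ext) - 1):
        if amps[k - 1] > sd and amps[k] > sd:
            first_valid = k
            break
    if first_valid is None:
        return 0.0
    valid = [a for a in amps if a > sd]
    return sum(valid) / len(valid)


def excursion_counts(day, upper, lower):
    values = collapse_plateaus(list(day))
    th = tl = 0
    for _, v, is_max in extrema(values):
        if is_max and v > upper:
            th += 1
        if not is_max and v < lower:
            tl += 1
    return th, tl


def time_percentages(day, upper, lower):
    hl = 100.0 * sum(1 for x in day if x > upper) / len(day)
    ll = 100.0 * sum(1 for x in day if x < lower) / len(day)
    return hl, ll, 100.0 - hl - ll
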