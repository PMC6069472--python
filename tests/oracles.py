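"""Independent brute-force oracles shared across test modules.

Everything here recomputes results directly from definitions (explicit
loops, sorted copies) and stays independent of the implementation paths it
is used to check.
"""

import numpy as np

# --- LBP-TOP: naive per-pixel recoding ------------------------------------

_OFFS = [(-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1)]


def u2_bin_map():
    binmap, nxt = {}, 0
    for code in range(256):
        bits = [(code >> i) & 1 for i in range(8)]
        if sum(bits[i] != bits[(i + 1) % 8] for i in range(8)) <= 2:
            binmap[code] = nxt
            nxt += 1
        else:
            binmap[code] = 58
    return binmap


def naive_lbp_top(vol):
    """Recode all three plane families pixel by pixel; unnormalized 177-histogram."""
    binmap = u2_bin_map()
    T, H, W = vol.shape
    hists = np.zeros((3, 59))

    def code_at(get, r, c):
        center = get(r, c)
        code = 0
        for b, (dr, dc) in enumerate(_OFFS):
            if get(r + dr, c + dc) >= center:
                code |= 1 << b
        return code

    for t in range(T):  # XY
        for y in range(1, H - 1):
            for x in range(1, W - 1):
                hists[0, binmap[code_at(lambda r, c: vol[t, r, c], y, x)]] += 1
    for y in range(H):  # XT: rows are t, cols are x
        for t in range(1, T - 1):
            for x in range(1, W - 1):
                hists[1, binmap[code_at(lambda r, c: vol[r, y, c], t, x)]] += 1
    for x in range(W):  # YT: rows are t, cols are y
        for t in range(1, T - 1):
            for y in range(1, H - 1):
                hists[2, binmap[code_at(lambda r, c: vol[r, c, x], t, y)]] += 1
    return np.concatenate(hists)


# --- temporal descriptors: per-definition recomputation -------------------

def _quantile(sorted_y, q):
    pos = q * (len(sorted_y) - 1)
    lo, hi = int(np.floor(pos)), int(np.ceil(pos))
    frac = pos - lo
    return sorted_y[lo] * (1 - frac) + sorted_y[hi] * frac


def oracle_describe(y, fs):
    y = [float(v) for v in y]
    n = len(y)
    s = sorted(y)
    y_max, y_min = max(y), min(y)
    mean = sum(y) / n
    median = _quantile(s, 0.5)
    half = (mean + y_min) / 2

    def runs(threshold):
        count, inside = 0, False
        for v in y:
            if v > threshold and not inside:
                count += 1
                inside = True
            elif v <= threshold:
                inside = False
        return count

    abs_dev = sorted(abs(v - median) for v in y)
    area = sum(v - y_min for v in y) / fs
    rng = y_max - y_min
    first_max = next(i for i, v in enumerate(y) if v == y_max)
    return {
        "max": y_max,
        "min": y_min,
        "mean": mean,
        "median": median,
        "range": rng,
        "std": (sum((v - mean) ** 2 for v in y) / n) ** 0.5,
        "iqr": _quantile(s, 0.75) - _quantile(s, 0.25),
        "idr": _quantile(s, 0.90) - _quantile(s, 0.10),
        "mad": _quantile(abs_dev, 0.5),
        "t_max": first_max / fs,
        "dur_above_mean": sum(1 for v in y if v > mean) / fs,
        "dur_above_halfmin": sum(1 for v in y if v > half) / fs,
        "seg_above_mean": float(runs(mean)),
        "seg_above_halfmin": float(runs(half)),
        "area": area,
        "area_quotient": area / rng if rng > 0 else 0.0,
    }


# --- AUC: pair counting ---------------------------------------------------

def pair_count_auc(scores, y):
    pos = [s for s, t in zip(scores, y) if t == 1]
    neg = [s for s, t in zip(scores, y) if t == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))
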