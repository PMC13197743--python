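"""Shared fixtures and independent oracle helpers.

Oracles here are deliberately naive (exhaustive scans, O(n^2) pair counts,
direct formula evaluation) and independent of the package's code paths.
"""

import numpy as np
import pandas as pd
import pytest

from oxiscreen.spo2_io import Spo2Signal


def make_signal(values, rate_hz=1.0, mask=None, subject_id="test"):
    values = np.asarray(values, dtype=np.float64)
    if mask is None:
        mask = np.isfinite(values)
    return Spo2Signal(values=values, rate_hz=rate_hz,
                      valid_mask=np.asarray(mask, dtype=bool), subject_id=subject_id)


def triangular_dip_signal(baseline=96.0, depth=10.0, half_width=30, pad=120):
    """Flat baseline with one symmetric triangular dip; returns (signal, nadir_idx)."""
    n = 2 * pad + 2 * half_width + 1
    values = np.full(n, baseline)
    nadir = pad + half_width
    for k in range(-half_width, half_width + 1):
        values[nadir + k] = baseline - depth * (1 - abs(k) / half_width)
    return make_signal(values), nadir


# ---------------------------------------------------------------------------
# oracles

def valley_scan_oracle(values, min_depth):
    """Exhaustive scan for local minima with two-sided topographic prominence
    >= min_depth (plateaus collapse to their first index)."""
    values = np.asarray(values, dtype=np.float64)
    n = len(values)
    out = []
    for i in range(n):
        left_neighbor = i - 1
        while left_neighbor >= 0 and values[left_neighbor] == values[i]:
            left_neighbor -= 1
        right_neighbor = i + 1
        while right_neighbor < n and values[right_neighbor] == values[i]:
            right_neighbor += 1
        if left_neighbor < 0 or right_neighbor >= n:
            continue  # edge plateau, not an interior minimum
        if not (values[left_neighbor] > values[i] and values[right_neighbor] > values[i]):
            continue
        if i > 0 and values[i - 1] == values[i]:
            continue  # not the first index of the plateau
        # climb left until ground lower-or-equal than the minimum
        left_max = -np.inf
        j = i - 1
        while j >= 0 and values[j] > values[i]:
            left_max = max(left_max, values[j])
            j -= 1
        right_max = -np.inf
        j = right_neighbor
        while j < n and values[j] > values[i]:
            right_max = max(right_max, values[j])
            j += 1
        if min(left_max, right_max) - values[i] >= min_depth:
            out.append(i)
    return out


def trapezoid_deficit_oracle(values, win_start, win_finish, baseline):
    """Baseline-deficit area by numpy.trapezoid over the closed window."""
    end = min(win_finish, len(values) - 1)
    deficit = np.maximum(0.0, baseline - np.asarray(values[win_start:end + 1]))
    return float(np.trapezoid(deficit))


def concordance_auc_oracle(scores, labels):
    """All-pairs concordance probability; ties count one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def histogram_entropy_oracle(intervals):
    from collections import Counter
    import math
    counts = Counter(intervals)
    n = sum(counts.values())
    return -sum((c / n) * math.log(c / n) for c in counts.values())


def lombscargle_oracle(t, y, freqs_hz):
    """Classical Lomb-Scargle periodogram from the defining formula."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float) - np.mean(y)
    out = np.empty(len(freqs_hz))
    for i, f in enumerate(freqs_hz):
        w = 2 * np.pi * f
        tau = np.arctan2(np.sum(np.sin(2 * w * t)), np.sum(np.cos(2 * w * t))) / (2 * w)
        c = np.cos(w * (t - tau))
        s = np.sin(w * (t - tau))
        out[i] = 0.5 * ((y @ c) ** 2 / (c @ c) + (y @ s) ** 2 / (s @ s))
    return out


# ---------------------------------------------------------------------------
# feature-table factory (fast, signal-free cohorts for the modeling layer)

def make_feature_table(n=200, prevalence=0.5, effect=3.0, seed=0,
                       with_demographics=True):
    """Synthetic 8-feature table with class-shifted means (no signals).

    `effect` is the between-class shift in units of the within-class SD;
    effect 0 gives pure noise (labels uninformative).
    """
    from oxiscreen.oximetry_summary import FEATURE_NAMES

    rng = np.random.default_rng(seed)
    n_pos = int(round(n * prevalence))
    y = np.array([1] * n_pos + [0] * (n - n_pos))
    rng.shuffle(y)
    base = {
        "MeanSpO2": (95.0, -0.4), "MinSpO2": (88.0, -2.0), "ODI": (5.0, 8.0),
        "T90": (5.0, 6.0), "ST90": (1.0, 2.0), "HB": (3.0, 6.0),
        "AttnEn": (1.8, 0.4), "TotalPower": (38.0, 1.0),
    }
    data = {}
    for name in FEATURE_NAMES:
        mu, delta = base[name]
        data[name] = mu + effect / 3.0 * delta * y + rng.normal(0, abs(delta) / 3.0 + 0.1, n)
    table = pd.DataFrame(data)
    table["label"] = y
    if with_demographics:
        table["subject_id"] = [f"s{i:04d}" for i in range(n)]
        table["sex"] = np.where(rng.random(n) < 0.75, "male", "female")
        table["age_years"] = rng.integers(25, 80, n)
        table["cohort"] = "internal"
    return table


@pytest.fixture
def feature_table():
    return make_feature_table(n=120, seed=11)
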