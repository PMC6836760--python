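"""Independent oracles used by the test suite.

These deliberately re-derive the stated rules in naive, transparent code
(plain loops, brute-force scans, rasterized areas) and never call into the
package's own implementations.
"""

from __future__ import annotations

import math

import numpy as np


def brute_force_fixations(
    t, x, y, valid, *,
    threshold=1.25, min_fix_ms=100.0, min_dev_ms=100.0, max_gap_ms=100.0,
    period_ms=1000.0 / 30.0, eps=1e-6,
):
    """Greedy left-to-right maximal fixation runs, evaluated exhaustively.

    A run grows from each candidate start sample: the next valid sample is
    accepted when it lies within `threshold` of the mean of all accepted
    samples; a spatial excursion is bridged when some later valid sample
    returns within threshold of the frozen mean in under `min_dev_ms`;
    invalid stretches up to `max_gap_ms` are bridged.  A run qualifies when
    (last accepted time + period - first time) >= `min_fix_ms`; otherwise
    the start slides one sample right.  Returns (onset, offset, accepted
    index tuple) triples with offset = last accepted time + period.
    """
    n = len(t)
    events = []
    start = 0
    while start < n:
        if not valid[start]:
            start += 1
            continue
        accepted = [start]
        k = start + 1
        while k < n:
            cx = sum(x[j] for j in accepted) / len(accepted)
            cy = sum(y[j] for j in accepted) / len(accepted)
            if not valid[k]:
                nxt = k
                while nxt < n and not valid[nxt]:
                    nxt += 1
                if nxt < n and t[nxt] - t[accepted[-1]] <= max_gap_ms + eps:
                    k = nxt
                    continue
                break
            if math.hypot(x[k] - cx, y[k] - cy) <= threshold:
                accepted.append(k)
                k += 1
                continue
            came_back = None
            m = k + 1
            while m < n and t[m] - t[k] < min_dev_ms - eps:
                if valid[m] and math.hypot(x[m] - cx, y[m] - cy) <= threshold:
                    came_back = m
                    break
                m += 1
            if came_back is None:
                break
            accepted.append(came_back)
            k = came_back + 1
        duration = t[accepted[-1]] + period_ms - t[accepted[0]]
        if duration >= min_fix_ms - eps:
            events.append(
                (float(t[accepted[0]]), float(t[accepted[-1]] + period_ms),
                 tuple(accepted))
            )
            start = accepted[-1] + 1
        else:
            start = accepted[0] + 1
    return events


def random_gaze_stream(rng, n=91, period_ms=1000.0 / 30.0):
    """A 3-second 30 Hz stream alternating dwells, drifts and jumps, with
    occasional invalid samples — adversarial input for detector/oracle
    agreement."""
    t = np.arange(n) * period_ms
    x = np.empty(n)
    y = np.empty(n)
    pos = rng.uniform(-5, 5, size=2)
    i = 0
    while i < n:
        kind = rng.choice(["dwell", "drift", "jump"], p=[0.5, 0.3, 0.2])
        length = int(rng.integers(1, 9))
        if kind == "jump":
            pos = pos + rng.uniform(-4, 4, size=2)
            length = 1
        for _ in range(length):
            if i >= n:
                break
            if kind == "drift":
                pos = pos + rng.uniform(-0.9, 0.9, size=2)
            x[i], y[i] = pos + rng.normal(0, 0.25, size=2)
            i += 1
    valid = rng.random(n) > 0.06
    return t, x, y, valid


def rasterized_aoi(cursor, radius, rects, rim_outer=None, rim_inner=None,
                   hoop_mid_y=0.0, grid=120):
    """Majority AOI by counting grid points inside the cursor disc.

    `rects` maps region name -> (xmin, ymin, xmax, ymax).  If rim bounds
    are given, points inside `rim_outer` but outside `rim_inner` count as
    rim and a rim majority resolves to backboard/net by cursor height.
    Returns (region or None, fraction dict).
    """
    cx, cy = cursor
    xs = np.linspace(cx - radius, cx + radius, grid)
    ys = np.linspace(cy - radius, cy + radius, grid)
    gx, gy = np.meshgrid(xs, ys)
    inside = (gx - cx) ** 2 + (gy - cy) ** 2 <= radius**2
    total = inside.sum()
    fracs = {}
    claimed = np.zeros_like(inside)
    for name, (x0, y0, x1, y1) in rects.items():
        hit = inside & (gx >= x0) & (gx <= x1) & (gy >= y0) & (gy <= y1)
        fracs[name] = hit.sum() / total
    if rim_outer is not None:
        x0, y0, x1, y1 = rim_outer
        outer = inside & (gx >= x0) & (gx <= x1) & (gy >= y0) & (gy <= y1)
        x0, y0, x1, y1 = rim_inner
        inner = inside & (gx >= x0) & (gx <= x1) & (gy >= y0) & (gy <= y1)
        fracs["__rim__"] = (outer & ~inner).sum() / total
    best = max(fracs, key=fracs.get)
    if fracs[best] <= 0.5:
        return None, fracs
    if best == "__rim__":
        return ("backboard" if cy > hoop_mid_y else "net"), fracs
    return best, fracs


def wilson_interval(k, n, z=1.959963984540054):
    """Closed-form Wilson score interval for a binomial proportion."""
    p = k / n
    denom = 1 + z**2 / n
    centre = (p + z**2 / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return centre - half, centre + half
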