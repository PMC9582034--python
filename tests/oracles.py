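"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a quantity from first principles (exhaustive
scans, direct morphological definitions, naive searches) so the package
implementations are checked against code that shares none of their
shortcuts.
"""

import numpy as np


def li_cross_entropy(values: np.ndarray, t: float) -> float:
    """Li & Lee minimum-cross-entropy criterion for a threshold t."""
    below = values[values <= t]
    above = values[values > t]
    if below.size == 0 or above.size == 0:
        return np.inf
    mu_b, mu_a = below.mean(), above.mean()
    return -(below.sum() * np.log(mu_b) + above.sum() * np.log(mu_a))


def li_exhaustive(values: np.ndarray) -> float:
    """Brute-force minimizer of the cross-entropy criterion.

    Scans the midpoints between consecutive sorted unique values.
    """
    uniq = np.unique(values)
    candidates = 0.5 * (uniq[:-1] + uniq[1:])
    scores = [li_cross_entropy(values, t) for t in candidates]
    return float(candidates[int(np.argmin(scores))])


def huang_fuzziness(levels, hist, t) -> float:
    """Huang & Wang measure of fuzziness for threshold t (naive)."""
    c = levels[-1] - levels[0]
    sel = levels <= t
    if hist[sel].sum() == 0 or hist[~sel].sum() == 0:
        return np.inf
    mu0 = (levels[sel] * hist[sel]).sum() / hist[sel].sum()
    mu1 = (levels[~sel] * hist[~sel]).sum() / hist[~sel].sum()
    total = 0.0
    for g, h in zip(levels, hist):
        if h == 0:
            continue
        mu = mu0 if g <= t else mu1
        u = 1.0 / (1.0 + abs(g - mu) / c)
        u = min(max(u, 1e-12), 1 - 1e-12)
        total += h * (-(u * np.log(u) + (1 - u) * np.log(1 - u)))
    return total


def huang_exhaustive(levels, hist) -> float:
    """Brute-force minimizer of Huang's fuzziness over all gray levels."""
    scores = [huang_fuzziness(levels, hist, t) for t in levels[:-1]]
    return float(levels[int(np.argmin(scores))])


def _shifted_extremum(vol, offsets, op):
    """Erosion/dilation by explicit shift-and-reduce with edge replication."""
    z, y, x = vol.shape
    zz, yy, xx = np.meshgrid(
        np.arange(z), np.arange(y), np.arange(x), indexing="ij"
    )
    out = None
    for dz, dy, dx in offsets:
        shifted = vol[
            np.clip(zz + dz, 0, z - 1),
            np.clip(yy + dy, 0, y - 1),
            np.clip(xx + dx, 0, x - 1),
        ]
        out = shifted if out is None else op(out, shifted)
    return out


def white_top_hat_bruteforce(vol: np.ndarray, diameter: int) -> np.ndarray:
    """Top-hat as vol - dilate(erode(vol)) with explicit shifted minima/maxima.

    Values beyond the border replicate the nearest voxel, the same
    boundary convention as the implementation.
    """
    r = diameter // 2
    offs = [
        (dz, dy, dx)
        for dz in range(-r, r + 1)
        for dy in range(-r, r + 1)
        for dx in range(-r, r + 1)
        if dz * dz + dy * dy + dx * dx <= (diameter / 2.0) ** 2
    ]
    eroded = _shifted_extremum(vol.astype(np.float64), offs, np.minimum)
    opened = _shifted_extremum(eroded, offs, np.maximum)
    return vol - opened


def wall_thickness_bruteforce(mask: np.ndarray) -> np.ndarray:
    """Largest-inscribed-digital-sphere diameter per voxel.

    For every candidate center, finds the largest integer radius R such
    that all in-grid voxels within distance R belong to the mask, then
    assigns the diameter 2R to every voxel the sphere covers.
    """
    mask = np.asarray(mask, dtype=bool)
    shape = np.array(mask.shape)
    centers = np.argwhere(mask)
    thickness = np.zeros(mask.shape)
    r_cap = int(max(mask.shape))
    for c in centers:
        r_best = -1
        for radius in range(r_cap):
            lo = np.maximum(c - radius, 0)
            hi = np.minimum(c + radius + 1, shape)
            sub = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
            grid = np.ogrid[sub]
            ball = sum((g - ci) ** 2 for g, ci in zip(grid, c)) <= radius**2
            if not mask[sub][ball].all():
                break
            r_best = radius
        if r_best < 0:
            continue
        lo = np.maximum(c - r_best, 0)
        hi = np.minimum(c + r_best + 1, shape)
        sub = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
        grid = np.ogrid[sub]
        ball = sum((g - ci) ** 2 for g, ci in zip(grid, c)) <= r_best**2
        region = thickness[sub]
        np.maximum(region, np.where(ball, 2 * r_best, 0), out=region)
    return thickness


def through_origin_fit(x, y):
    """Closed-form zero-intercept regression evaluated naively."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    slope = sum(a * b for a, b in zip(x, y)) / sum(a * a for a in x)
    ss_res = sum((b - slope * a) ** 2 for a, b in zip(x, y))
    ss_tot = sum(b * b for b in y)
    return slope, 1 - ss_res / ss_tot
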