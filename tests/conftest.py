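import numpy as np
import pytest

from fetpet import CLASS_KINETICS, FrameSchedule, simulate_dynamic_series

SMALL_GRID = (32, 32, 32)


@pytest.fixture(scope="session")
def schedule():
    return FrameSchedule.default()


@pytest.fixture(scope="session")
def noise_free_phantoms():
    """One noise-free small-grid phantom per TAC class."""
    out = {}
    for name, kin in CLASS_KINETICS.items():
        out[name] = simulate_dynamic_series(
            kin, background_suv=1.0, noise_sd=0.0, grid_shape=SMALL_GRID, seed=0
        )
    return out


def random_phantom_kinetics(rng):
    """Random lesion kinetics spanning the three curve classes.

    Amplitudes and washout rates are kept in the clinically plausible range
    where the lesion remains above the 1.6x-background contour cutoff in the
    20-40-min window (a lesion that washes out below background contrast is
    not a segmentation test case).
    """
    from fetpet import LesionKinetics

    tac_class = rng.choice(["descending", "plateau", "ascending"])
    amplitude = rng.uniform(3.0, 5.0)
    if tac_class == "descending":
        return LesionKinetics(amplitude, rng.uniform(0.4, 0.7), rng.uniform(0.006, 0.012),
                              "descending")
    if tac_class == "plateau":
        return LesionKinetics(amplitude, rng.uniform(0.4, 0.7), rng.uniform(0.0008, 0.0015),
                              "plateau")
    return LesionKinetics(amplitude, rng.uniform(0.05, 0.1), 0.0, "ascending")


# ---------------------------------------------------------------------------
# independent oracles (kept deliberately naive)
# ---------------------------------------------------------------------------


def bruteforce_auc(values, labels_tp):
    """AUC by counting concordant positive-negative pairs; ties count 1/2."""
    pos = [v for v, y in zip(values, labels_tp) if y]
    neg = [v for v, y in zip(values, labels_tp) if not y]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def bruteforce_youden(values, labels_tp):
    """Exhaustive scan of all midpoint thresholds (rule: value >= t -> TP)."""
    values = np.asarray(values, float)
    labels_tp = np.asarray(labels_tp, bool)
    uniq = np.unique(values)
    cands = [-np.inf] + [(a + b) / 2 for a, b in zip(uniq[:-1], uniq[1:])] + [np.inf]
    best = None
    for t in cands:
        pred = values >= t
        sens = (pred & labels_tp).sum() / labels_tp.sum()
        spec = (~pred & ~labels_tp).sum() / (~labels_tp).sum()
        j = sens + spec - 1
        key = (j, sens, -t)  # ties: higher sens, then lower threshold
        if best is None or key > best[0]:
            best = (key, t, j)
    return best[1], best[2]


def enumerate_mwu_p(x, y):
    """Exact two-sided MWU p-value by full enumeration of rank assignments."""
    from itertools import combinations

    x, y = list(x), list(y)
    m, n = len(x), len(y)
    combined = sorted(x + y)
    assert len(set(combined)) == m + n, "enumeration oracle assumes no ties"

    def u_stat(xs, ys):
        return sum(1 for a in xs for b in ys if a > b)

    u_obs = u_stat(x, y)
    mu = m * n / 2
    count = 0
    total = 0
    for idx in combinations(range(m + n), m):
        xs = [combined[i] for i in idx]
        ys = [combined[i] for i in range(m + n) if i not in idx]
        u = u_stat(xs, ys)
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
        total += 1
    return count / total


def flood_fill_26(above, seed):
    """Naive BFS 26-connected component of ``seed`` within boolean ``above``."""
    from collections import deque

    if not above[seed]:
        return np.zeros_like(above)
    comp = np.zeros_like(above)
    comp[seed] = True
    q = deque([seed])
    shape = above.shape
    while q:
        x, y, z = q.popleft()
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    if dx == dy == dz == 0:
                        continue
                    p = (x + dx, y + dy, z + dz)
                    if all(0 <= p[a] < shape[a] for a in range(3)):
                        if above[p] and not comp[p]:
                            comp[p] = True
                            q.append(p)
    return comp
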