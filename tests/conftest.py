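import numpy as np
import pytest

from arcmetrics import Arc, ControlPoint, MLCBankPositions, Plan


def make_mlc(left, right, t=5.0) -> MLCBankPositions:
    return MLCBankPositions(np.asarray(left, float), np.asarray(right, float), t)


def make_arc(mlcs, weights=None, arc_mu=100.0, increment=30.0, direction="CW") -> Arc:
    """Toy arc from a list of MLC snapshots, gantry spread over 360 deg."""
    n = len(mlcs)
    if weights is None:
        weights = np.linspace(0.0, 1.0, n)
    angles = np.linspace(0.0, 360.0, n) % 360.0
    cps = [
        ControlPoint(gantry_deg=a, mlc=m, cum_weight=w)
        for a, m, w in zip(angles, mlcs, weights)
    ]
    return Arc(control_points=cps, arc_mu=arc_mu, increment_deg=increment,
               direction=direction)


def make_plan(arcs, **kwargs) -> Plan:
    return Plan(arcs=arcs, **kwargs)


def random_mlc(rng, n_pairs=5, t=5.0, closed_prob=0.2) -> MLCBankPositions:
    """Random aperture with occasional closed pairs."""
    left = rng.uniform(-60.0, 0.0, n_pairs)
    right = left + rng.uniform(2.0, 60.0, n_pairs)
    closed = rng.random(n_pairs) < closed_prob
    mid = 0.5 * (left[closed] + right[closed])
    left[closed] = mid
    right[closed] = mid
    return MLCBankPositions(left, right, t)


def random_arc(rng, n_cp=5, n_pairs=5, t=5.0, closed_prob=0.2) -> Arc:
    mlcs = [random_mlc(rng, n_pairs, t, closed_prob) for _ in range(n_cp)]
    w = np.sort(rng.uniform(0.0, 1.0, n_cp))
    w[0], w[-1] = 0.0, 1.0
    return make_arc(mlcs, weights=w, arc_mu=float(rng.uniform(50.0, 500.0)))


@pytest.fixture
def rng():
    return np.random.default_rng(20240)
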