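import numpy as np
import pytest

from incluflux.detect import SpotCandidate
from incluflux.simulate import AcquisitionConfig


@pytest.fixture
def quiet_config():
    """Noise-free acquisition for deterministic rendering tests."""
    return AcquisitionConfig(shot_noise=False, read_noise_sd=0.0,
                             background_level=10.0)


def make_candidates(per_frame_xys, scores=None):
    """Build per-frame SpotCandidate lists from (x, y) tuples.

    ``per_frame_xys`` is a list (one entry per frame) of lists of (x, y)
    positions; ``scores`` optionally parallels it.
    """
    out = []
    for f, frame in enumerate(per_frame_xys):
        cands = []
        for j, (x, y) in enumerate(frame):
            s = scores[f][j] if scores is not None else 1.0
            cands.append(SpotCandidate(frame=f, x_px=float(x), y_px=float(y),
                                       score=float(s), raw_intensity=float(s),
                                       size_px=2))
        out.append(cands)
    return out


def brute_force_best_score(per_frame, params, field_shape=None):
    """Exhaustive path enumeration oracle for the tracker objective.

    Recomputes the documented score for every index combination with its
    own arithmetic (independent of the DP) and returns the maximum.
    """
    import itertools

    scores = [c.score for fr in per_frame for c in fr]
    lo, hi = min(scores), max(scores)
    span = hi - lo
    norm = [
        [1.0 if span == 0 else (c.score - lo) / span for c in fr] for fr in per_frame
    ]
    best = -np.inf
    for combo in itertools.product(*[range(len(fr)) for fr in per_frame]):
        total = 0.0
        feasible = True
        prev = None
        for f, j in enumerate(combo):
            c = per_frame[f][j]
            total += params.w_intensity * norm[f][j]
            if field_shape is not None and params.w_center > 0:
                h, w = field_shape
                cy, cx = (h - 1) / 2, (w - 1) / 2
                rad = np.hypot(cy, cx)
                total -= params.w_center * np.hypot(c.y_px - cy, c.x_px - cx) / rad
            if prev is not None:
                pf, pj = prev
                pc = per_frame[pf][pj]
                step = np.hypot(c.x_px - pc.x_px, c.y_px - pc.y_px)
                if step > params.max_displacement_px:
                    feasible = False
                    break
                total += params.w_intensity_variation * (1 - abs(norm[f][j] - norm[pf][pj]))
                total -= params.w_movement * step / params.max_displacement_px
            prev = (f, j)
        if feasible and total > best:
            best = total
    return best
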