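"""Single-particle linking by dynamic programming.

Links per-frame spot candidates into the single globally optimal path for a
movie cropped around one particle.  The path maximises a weighted score
combining filter response, frame-to-frame response stability, a movement
penalty, and an (inert by default) centre-proximity penalty, subject to a
hard per-step displacement bound; the optimum is found exactly by per-frame
dynamic programming over candidate nodes.

A missed detection (empty frame) or an infeasible step breaks the track:
the longest feasible leading segment is returned with a diagnostic, because
downstream MSD analysis requires contiguous frames.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .detect import SpotCandidate
from .types import Track

__all__ = ["TrackingParams", "track_particle", "path_score"]

_EPS = 1e-12


@dataclass
class TrackingParams:
    """Linking weights and displacement bound.

    Defaults follow the tracking parameter set used throughout the package:
    maximum displacement 10 px, intensity weight 0.80, intensity-variation
    weight 0.20, movement constraint 0.40 and centre constraint 0.00.
    """

    max_displacement_px: float = 10.0
    w_intensity: float = 0.80
    w_intensity_variation: float = 0.20
    w_movement: float = 0.40
    w_center: float = 0.00

    def __post_init__(self) -> None:
        if self.max_displacement_px <= 0:
            raise ValueError("max_displacement_px must be positive")
        for w in (self.w_intensity, self.w_intensity_variation,
                  self.w_movement, self.w_center):
            if w < 0:
                raise ValueError("weights must be non-negative")


def _normalize_scores(per_frame: Sequence[Sequence[SpotCandidate]]) -> list[np.ndarray]:
    """Min-max normalise candidate responses over the whole movie."""
    scores = [c.score for frame in per_frame for c in frame]
    if not scores:
        return [np.empty(0) for _ in per_frame]
    lo, hi = min(scores), max(scores)
    span = hi - lo
    out = []
    for frame in per_frame:
        if span < _EPS:
            out.append(np.ones(len(frame)))
        else:
            out.append(np.array([(c.score - lo) / span for c in frame]))
    return out


def _center_penalties(
    per_frame: Sequence[Sequence[SpotCandidate]],
    field_shape: Optional[tuple[int, int]],
) -> list[np.ndarray]:
    if field_shape is None:
        return [np.zeros(len(f)) for f in per_frame]
    h, w = field_shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    radius = max(np.hypot(cy, cx), _EPS)
    return [
        np.array([np.hypot(c.y_px - cy, c.x_px - cx) / radius for c in frame])
        for frame in per_frame
    ]


def path_score(
    per_frame: Sequence[Sequence[SpotCandidate]],
    indices: Sequence[int],
    params: TrackingParams,
    field_shape: Optional[tuple[int, int]] = None,
) -> float:
    """Total score of a specific candidate path (one index per frame).

    Defines the objective the tracker maximises; exposed so that
    alternative path searches can be scored identically.  Returns −inf if
    any step exceeds the displacement bound.
    """
    norm = _normalize_scores(per_frame)
    cent = _center_penalties(per_frame, field_shape)
    total = 0.0
    prev = None
    for f, j in enumerate(indices):
        c = per_frame[f][j]
        total += params.w_intensity * norm[f][j] - params.w_center * cent[f][j]
        if prev is not None:
            pf, pj = prev
            pc = per_frame[pf][pj]
            step = np.hypot(c.x_px - pc.x_px, c.y_px - pc.y_px)
            if step > params.max_displacement_px:
                return -np.inf
            total += params.w_intensity_variation * (1.0 - abs(norm[f][j] - norm[pf][pj]))
            total -= params.w_movement * step / params.max_displacement_px
        prev = (f, j)
    return float(total)


def track_particle(
    per_frame: Sequence[Sequence[SpotCandidate]],
    params: Optional[TrackingParams] = None,
    start_hint: Optional[tuple[float, float]] = None,
    pixel_size_um: float = 1.0,
    frame_interval_s: float = 1.0,
    field_shape: Optional[tuple[int, int]] = None,
) -> Track:
    """Link candidates into the globally optimal single-particle path.

    ``per_frame`` is one candidate list per movie frame, in frame order.
    ``start_hint`` (x, y in px) restricts the first linked frame to
    candidates within the displacement bound of the hint (falling back to
    the nearest candidate if none qualify).  Ties are broken by higher raw
    response, then lower candidate index.

    The returned :class:`Track` has positions in μm.  If the path breaks
    (empty frame or no feasible step), the longest feasible leading segment
    is returned and ``track.diagnostic`` describes the break.
    """
    if params is None:
        params = TrackingParams()
    if params.w_center > 0 and field_shape is None:
        raise ValueError("field_shape is required when w_center > 0")
    n_nonempty = sum(1 for f in per_frame if len(f) > 0)
    if n_nonempty < 2:
        raise ValueError("need candidates in at least 2 frames")

    norm = _normalize_scores(per_frame)
    cent = _center_penalties(per_frame, field_shape)

    first = next(i for i, f in enumerate(per_frame) if len(f) > 0)
    diagnostic = None

    # admissible candidates of the first frame, honouring the start hint
    first_cands = list(range(len(per_frame[first])))
    if start_hint is not None:
        hx, hy = start_hint
        dists = [np.hypot(per_frame[first][j].x_px - hx, per_frame[first][j].y_px - hy)
                 for j in first_cands]
        near = [j for j, d in zip(first_cands, dists) if d <= params.max_displacement_px]
        first_cands = near if near else [int(np.argmin(dists))]

    # forward DP; scores[f][j] = best path score ending at candidate j
    best = {j: params.w_intensity * norm[first][j] - params.w_center * cent[first][j]
            for j in first_cands}
    back: list[dict[int, Optional[int]]] = [{j: None for j in first_cands}]
    frames_used = [first]

    f = first
    while f + 1 < len(per_frame):
        nxt = f + 1
        if len(per_frame[nxt]) == 0:
            diagnostic = f"track broken: no candidates in frame {nxt}"
            break
        new_best: dict[int, float] = {}
        new_back: dict[int, Optional[int]] = {}
        for j, cj in enumerate(per_frame[nxt]):
            options = []
            for i in best:
                ci = per_frame[f][i]
                step = np.hypot(cj.x_px - ci.x_px, cj.y_px - ci.y_px)
                if step > params.max_displacement_px:
                    continue
                gain = (params.w_intensity_variation
                        * (1.0 - abs(norm[nxt][j] - norm[f][i]))
                        - params.w_movement * step / params.max_displacement_px)
                options.append((best[i] + gain, per_frame[f][i].score, -i, i))
            if not options:
                continue
            options.sort(reverse=True)
            score, _, _, pred = options[0]
            new_best[j] = (score + params.w_intensity * norm[nxt][j]
                           - params.w_center * cent[nxt][j])
            new_back[j] = pred
        if not new_best:
            diagnostic = (f"track broken: no step from frame {f} to {nxt} "
                          f"within {params.max_displacement_px} px")
            break
        best, f = new_best, nxt
        back.append(new_back)
        frames_used.append(nxt)

    # pick terminal node: best score, then higher response, then lower index
    term = sorted(best, key=lambda j: (-best[j], -per_frame[frames_used[-1]][j].score, j))[0]
    idx = [term]
    for level in range(len(back) - 1, 0, -1):
        idx.append(back[level][idx[-1]])
    idx.reverse()

    chosen = [per_frame[fr][j] for fr, j in zip(frames_used, idx)]
    frames = np.array(frames_used)
    track = Track(
        frames=frames,
        t_s=frames * frame_interval_s,
        x_um=np.array([c.x_px for c in chosen]) * pixel_size_um,
        y_um=np.array([c.y_px for c in chosen]) * pixel_size_um,
        intensity=np.array([c.raw_intensity for c in chosen]),
        pixel_size_um=pixel_size_um,
        frame_interval_s=frame_interval_s,
        diagnostic=diagnostic,
    )
    return track
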