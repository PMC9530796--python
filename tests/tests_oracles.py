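"""Brute-force reference implementations used only as test oracles."""

import numpy as np
from scipy.optimize import linear_sum_assignment


def nms_oracle(frame, theta, radius):
    """Independent per-frame NMS: double loop over pixels.

    A pixel is a candidate if it exceeds theta and no pixel within the
    Euclidean radius is strictly greater.  Candidates are then accepted
    greedily in (score desc, row-major) order, each suppressing later
    equal-valued candidates within the radius.
    """
    H, W = frame.shape
    candidates = []
    for y in range(H):
        for x in range(W):
            v = frame[y, x]
            if v <= theta:
                continue
            is_max = True
            for yy in range(H):
                for xx in range(W):
                    if (yy - y) ** 2 + (xx - x) ** 2 <= radius**2 and (
                        frame[yy, xx] > v
                    ):
                        is_max = False
                        break
                if not is_max:
                    break
            if is_max:
                candidates.append((x, y, v))
    candidates.sort(key=lambda c: (-c[2], c[1], c[0]))
    accepted = []
    for x, y, v in candidates:
        if all((y - ya) ** 2 + (x - xa) ** 2 > radius**2
               for xa, ya, _ in accepted):
            accepted.append((x, y, v))
    return accepted


def matching_oracle(dets, truth_points, gate):
    """Maximum number of one-to-one matches within the distance gate,
    via optimal assignment (upper bound the greedy matcher must reach
    on small instances)."""
    if not len(dets) or not len(truth_points):
        return 0
    d = np.array([
        [np.hypot(det.x - tx, det.y - ty) for tx, ty in truth_points]
        for det in dets
    ])
    cost = (d > gate).astype(float)
    ri, ci = linear_sum_assignment(cost)
    return int(np.sum(d[ri, ci] <= gate))
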