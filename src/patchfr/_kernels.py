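"""Numba kernels for the feeding-trial simulator.

The kernels use numba's ``np.random`` (legacy Mersenne-Twister) so that the
pure-Python reference engine in :mod:`patchfr.ibm`, driven by
``numpy.random.RandomState`` with the same seed and the same draw order,
produces bit-identical trials.  Keep the draw order in both engines in sync:

1. prey initial positions (2 uniforms each, in index order)
2. predator initial position (2 uniforms)
3. each step: one angle per prey (index order); then, if the predator moves,
   one angle; on encounter one target-selection uniform and one attack
   uniform; on success two uniforms for the replacement prey position.
"""

import numpy as np
from numba import njit

# keep cell indices strictly inside the grid when an individual stops on a wall
WALL_EPS = 1e-9


@njit(cache=True)
def _move(x, y, dist, angle, width, height):
    """Displace (x, y) by dist along angle, stopping at the first wall hit.

    sin is recovered from cos via the Pythagorean identity (sign flipped on
    (pi, 2*pi)); cheaper than a second libm call in the hot prey loop.
    """
    c = np.cos(angle)
    s = np.sqrt(1.0 - c * c)
    if angle > np.pi:
        s = -s
    dx = c * dist
    dy = s * dist
    t = 1.0
    if dx > 0.0:
        lim = (width - WALL_EPS - x) / dx
        if lim < t:
            t = lim
    elif dx < 0.0:
        lim = -x / dx
        if lim < t:
            t = lim
    if dy > 0.0:
        lim = (height - WALL_EPS - y) / dy
        if lim < t:
            t = lim
    elif dy < 0.0:
        lim = -y / dy
        if lim < t:
            t = lim
    if t < 0.0:
        t = 0.0
    nx = x + t * dx
    ny = y + t * dy
    # guard against one-ulp overshoot of the wall from the rounding of x+t*dx
    if nx < 0.0:
        nx = 0.0
    elif nx > width - WALL_EPS:
        nx = width - WALL_EPS
    if ny < 0.0:
        ny = 0.0
    elif ny > height - WALL_EPS:
        ny = height - WALL_EPS
    return nx, ny


@njit(cache=True)
def run_trial_kernel(
    width,
    height,
    refuge_flat,
    n_prey,
    n_steps,
    step_pred,
    step_prey,
    digestion_per_step,
    gut_capacity,
    gut_init,
    gut_threshold,
    handling_steps,
    attack_p,
    prey_mass,
    seed,
):
    """One spatial feeding trial; returns the number of prey eaten.

    Each step: all prey random-walk, then the predator digests and — unless
    handling or satiated (gut >= gut_threshold * capacity) — random-walks and
    attacks one uniformly chosen prey sharing its cell, provided the cell is
    not a refuge.  A successful attack teleports the victim to a uniformly
    random position (instant replacement keeps prey density constant).
    """
    np.random.seed(seed)
    w = float(width)
    h = float(height)
    two_pi = 2.0 * np.pi

    px = np.empty(n_prey, np.float64)
    py = np.empty(n_prey, np.float64)
    pcell = np.empty(n_prey, np.int64)
    counts = np.zeros(width * height, np.int32)
    for i in range(n_prey):
        px[i] = np.random.random() * w
        py[i] = np.random.random() * h
        c = int(py[i]) * width + int(px[i])
        pcell[i] = c
        counts[c] += 1
    qx = np.random.random() * w
    qy = np.random.random() * h

    gut = gut_init
    handling = 0
    eaten = 0
    thresh = gut_threshold * gut_capacity

    for _ in range(n_steps):
        for i in range(n_prey):
            ang = two_pi * np.random.random()
            nx, ny = _move(px[i], py[i], step_prey, ang, w, h)
            px[i] = nx
            py[i] = ny
            c = int(ny) * width + int(nx)
            if c != pcell[i]:
                counts[pcell[i]] -= 1
                counts[c] += 1
                pcell[i] = c

        gut -= digestion_per_step
        if gut < 0.0:
            gut = 0.0
        if handling > 0:
            handling -= 1
        elif gut >= thresh:
            pass  # satiated: rest
        else:
            ang = two_pi * np.random.random()
            qx, qy = _move(qx, qy, step_pred, ang, w, h)
            c = int(qy) * width + int(qx)
            if (not refuge_flat[c]) and counts[c] > 0:
                t = int(np.random.random() * counts[c])
                if t >= counts[c]:
                    t = counts[c] - 1
                idx = -1
                seen = 0
                for i in range(n_prey):
                    if pcell[i] == c:
                        if seen == t:
                            idx = i
                            break
                        seen += 1
                if np.random.random() < attack_p:
                    eaten += 1
                    gut += prey_mass
                    handling = handling_steps
                    px[idx] = np.random.random() * w
                    py[idx] = np.random.random() * h
                    nc = int(py[idx]) * width + int(px[idx])
                    counts[c] -= 1
                    counts[nc] += 1
                    pcell[idx] = nc
    return eaten
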