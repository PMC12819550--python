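"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written with different primitives than the
package (BFS flood fill instead of skimage labelling, np.polyfit instead of
explicit normal equations) so agreement is a genuine cross-check.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def flood_fill_components(mask: np.ndarray) -> list[np.ndarray]:
    """8-connected components of a boolean mask via BFS; list of (n, 2) coords."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    comps = []
    ny, nx = mask.shape
    for i in range(ny):
        for j in range(nx):
            if mask[i, j] and not seen[i, j]:
                q = deque([(i, j)])
                seen[i, j] = True
                comp = []
                while q:
                    a, b = q.popleft()
                    comp.append((a, b))
                    for da in (-1, 0, 1):
                        for db in (-1, 0, 1):
                            na, nb = a + da, b + db
                            if 0 <= na < ny and 0 <= nb < nx and mask[na, nb] and not seen[na, nb]:
                                seen[na, nb] = True
                                q.append((na, nb))
                comps.append(np.array(comp))
    return comps


def oracle_detect(slice_hu, pixel_y, pixel_x, center_yx, window_mm=30.0,
                  threshold_hu=600.0, weighted=True):
    """Exhaustive window -> threshold -> flood fill -> (weighted) center."""
    cy, cx = center_yx
    half = window_mm / 2.0
    iy = np.nonzero((pixel_y >= cy - half) & (pixel_y <= cy + half))[0]
    ix = np.nonzero((pixel_x >= cx - half) & (pixel_x <= cx + half))[0]
    if len(iy) == 0 or len(ix) == 0:
        return []
    sub = slice_hu[iy[0] : iy[-1] + 1, ix[0] : ix[-1] + 1]
    ys = pixel_y[iy[0] : iy[-1] + 1]
    xs = pixel_x[ix[0] : ix[-1] + 1]
    mask = sub >= threshold_hu
    comps = flood_fill_components(mask)
    claimed = set()
    for comp in comps:
        claimed |= {(a, b) for a, b in comp}
    if weighted:
        below = sub[~mask]
        background = np.median(below) if below.size else 0.0
    centers = []
    ny, nx = sub.shape
    for comp in comps:
        if weighted:
            own = {(a, b) for a, b in comp}
            support = set(own)
            for a, b in own:  # one-pixel dilation by set expansion
                for da in (-1, 0, 1):
                    for db in (-1, 0, 1):
                        na, nb = a + da, b + db
                        if 0 <= na < ny and 0 <= nb < nx:
                            if (na, nb) not in claimed or (na, nb) in own:
                                support.add((na, nb))
            pix = np.array(sorted(support))
            rr, cc = pix[:, 0], pix[:, 1]
            w = np.maximum(sub[rr, cc] - background, 0.0)
            centers.append(np.array([np.average(ys[rr], weights=w),
                                     np.average(xs[cc], weights=w)]))
        else:
            rr, cc = comp[:, 0], comp[:, 1]
            centers.append(np.array([ys[rr].mean(), xs[cc].mean()]))
    return centers


def oracle_nearest(centers, prev_yx):
    best = None
    best_key = None
    for c in centers:
        key = (np.hypot(c[0] - prev_yx[0], c[1] - prev_yx[1]), c[0], c[1])
        if best_key is None or key < best_key:
            best_key = key
            best = c
    return best


def oracle_fit_direction(points, extent_mm=10.0):
    """np.polyfit-based distal line fit; returns (anchor, unit direction to tip)."""
    pts = np.asarray(points, dtype=float)
    pts = pts[np.argsort(pts[:, 0])]
    dz = np.median(np.abs(np.diff(pts[:, 0])))
    n_sel = max(2, int(round(extent_mm / dz)))
    sel = pts[-n_sel:]
    cy = np.polyfit(sel[:, 0], sel[:, 1], 1)
    cx = np.polyfit(sel[:, 0], sel[:, 2], 1)
    d = np.array([1.0, cy[0], cx[0]])
    d /= np.linalg.norm(d)
    if d[0] > 0:
        d = -d
    anchor = np.array([sel[-1, 0], np.polyval(cy, sel[-1, 0]), np.polyval(cx, sel[-1, 0])])
    return anchor, d


def oracle_line_at_z(anchor, direction, z):
    t = (z - anchor[0]) / direction[0]
    return anchor + t * direction


def oracle_reconstruct(volume, tip_seed, template, margin_mm=2.0, window_mm=30.0,
                       threshold_hu=600.0, weighted=True):
    """Exhaustive per-slice reconstruction replicating the full procedure."""
    py, px = volume.pixel_centers()
    k = volume.slice_index(tip_seed[0])
    points = [np.array([volume.slice_z(k), tip_seed[1], tip_seed[2]])]
    stop_z = template.z_body_border - margin_mm
    # body-side trace
    while True:
        k += 1
        if k >= volume.shape[0] or volume.slice_z(k) > stop_z:
            break
        centers = oracle_detect(volume.voxels[k], py, px, points[-1][1:],
                                window_mm, threshold_hu, weighted)
        if not centers:
            return np.array(points)
        c = oracle_nearest(centers, points[-1][1:])
        points.append(np.array([volume.slice_z(k), c[0], c[1]]))
    if k >= volume.shape[0]:
        return np.array(points)
    # bridge
    anchor, d = oracle_fit_direction(np.array(points))
    k_ex = volume.slice_index(template.z_air_border + margin_mm)
    k_from = volume.slice_index(points[-1][0]) + 1
    for kk in range(k_from, k_ex + 1):
        points.append(oracle_line_at_z(anchor, d, volume.slice_z(kk)))
    # air-side trace
    k = k_ex
    while True:
        k += 1
        if k >= volume.shape[0]:
            break
        centers = oracle_detect(volume.voxels[k], py, px, points[-1][1:],
                                window_mm, threshold_hu, weighted)
        if not centers:
            break
        c = oracle_nearest(centers, points[-1][1:])
        points.append(np.array([volume.slice_z(k), c[0], c[1]]))
    return np.array(points)
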