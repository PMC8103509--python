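"""Independent brute-force references used by the tests.

Everything here is deliberately naive — nested loops, explicit
neighborhood walks, flood fill — and shares no code with the package's
vectorized implementations.
"""

from __future__ import annotations

import numpy as np

NEIGHBORS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def direct_ccc(x, y) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    sx2 = sum((a - mx) ** 2 for a in x) / n
    sy2 = sum((b - my) ** 2 for b in y) / n
    den = sx2 + sy2 + (mx - my) ** 2
    return 1.0 if den == 0 else 2 * sxy / den


def _inb(shape, p):
    return all(0 <= c < s for c, s in zip(p, shape))


def naive_glcm(lev, valid, ng, directions):
    out = np.zeros((ng, ng, len(directions)))
    nx, ny, nz = lev.shape
    for a, (dx, dy, dz) in enumerate(directions):
        for x in range(nx):
            for y in range(ny):
                for z in range(nz):
                    if not valid[x, y, z]:
                        continue
                    q = (x + dx, y + dy, z + dz)
                    if _inb(lev.shape, q) and valid[q]:
                        i, j = lev[x, y, z] - 1, lev[q] - 1
                        out[i, j, a] += 1
                        out[j, i, a] += 1
    return out


def naive_glrlm(lev, valid, ng, directions):
    max_run = max(lev.shape) * 2
    out = np.zeros((ng, max_run, len(directions)))
    nx, ny, nz = lev.shape
    for a, d in enumerate(directions):
        for x in range(nx):
            for y in range(ny):
                for z in range(nz):
                    p = (x, y, z)
                    if not valid[p]:
                        continue
                    prev = (x - d[0], y - d[1], z - d[2])
                    if _inb(lev.shape, prev) and valid[prev] and lev[prev] == lev[p]:
                        continue  # not a run start
                    length = 1
                    q = (x + d[0], y + d[1], z + d[2])
                    while _inb(lev.shape, q) and valid[q] and lev[q] == lev[p]:
                        length += 1
                        q = (q[0] + d[0], q[1] + d[1], q[2] + d[2])
                    out[lev[p] - 1, length - 1, a] += 1
    used = 1
    for l in range(max_run):
        if out[:, l, :].any():
            used = l + 1
    return out[:, :used, :]


def naive_glszm(lev, valid, ng):
    zones = []
    seen = np.zeros(lev.shape, bool)
    nx, ny, nz = lev.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not valid[x, y, z] or seen[x, y, z]:
                    continue
                level = lev[x, y, z]
                stack, size = [(x, y, z)], 0
                seen[x, y, z] = True
                while stack:
                    p = stack.pop()
                    size += 1
                    for d in NEIGHBORS_26:
                        q = (p[0] + d[0], p[1] + d[1], p[2] + d[2])
                        if (
                            _inb(lev.shape, q)
                            and valid[q]
                            and not seen[q]
                            and lev[q] == level
                        ):
                            seen[q] = True
                            stack.append(q)
                zones.append((level, size))
    max_size = max(s for _, s in zones)
    out = np.zeros((ng, max_size))
    for level, size in zones:
        out[level - 1, size - 1] += 1
    return out


def naive_gldm(lev, valid, ng, alpha=0):
    deps = []
    nx, ny, nz = lev.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not valid[x, y, z]:
                    continue
                dep = 0
                for d in NEIGHBORS_26:
                    q = (x + d[0], y + d[1], z + d[2])
                    if _inb(lev.shape, q) and valid[q] and abs(
                        int(lev[q]) - int(lev[x, y, z])
                    ) <= alpha:
                        dep += 1
                deps.append((lev[x, y, z], dep))
    max_dep = max(d for _, d in deps)
    out = np.zeros((ng, max_dep + 1))
    for level, dep in deps:
        out[level - 1, dep] += 1
    return out


def naive_ngtdm(lev, valid, ng):
    n_i = np.zeros(ng)
    s_i = np.zeros(ng)
    nx, ny, nz = lev.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not valid[x, y, z]:
                    continue
                nb = [
                    lev[x + d[0], y + d[1], z + d[2]]
                    for d in NEIGHBORS_26
                    if _inb(lev.shape, (x + d[0], y + d[1], z + d[2]))
                    and valid[x + d[0], y + d[1], z + d[2]]
                ]
                if not nb:
                    continue
                i = lev[x, y, z]
                n_i[i - 1] += 1
                s_i[i - 1] += abs(i - sum(nb) / len(nb))
    return n_i, s_i
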