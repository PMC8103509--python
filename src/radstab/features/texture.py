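"""Feature formulas for the five texture-matrix families.

GLCM and GLRLM features are evaluated per 3-D direction and arithmetically
averaged over the 13 directions; GLSZM, GLDM and NGTDM are single-pass
3-D (26-connectivity). Division-by-zero guards return the documented
limit value of each formula so a degenerate (e.g. constant) ROI still
produces finite numbers: a single-level GLCM has Correlation 1 and
Imc1/Imc2 0, a zero NGTDM coarseness denominator is capped at 1e6, etc.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "gldm_features",
    "ngtdm_features",
]

_COARSENESS_CAP = 1.0e6


def _entropy2(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


# ---------------------------------------------------------------- GLCM


def _glcm_one(P: np.ndarray) -> dict[str, float]:
    ng = P.shape[0]
    total = P.sum()
    if total == 0:
        raise ValueError("empty co-occurrence matrix")
    P = P / total
    i = np.arange(1, ng + 1, dtype=np.float64)
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    ux = float(np.sum(i * px))
    uy = float(np.sum(i * py))
    sx2 = float(np.sum((i - ux) ** 2 * px))
    sy2 = float(np.sum((i - uy) ** 2 * py))
    ii, jj = np.meshgrid(i, i, indexing="ij")

    # p_{x-y}(k), k = 0..ng-1 and p_{x+y}(k), k = 2..2ng
    k_diff = np.abs(ii - jj).astype(np.int64)
    p_diff = np.bincount(k_diff.ravel(), weights=P.ravel(), minlength=ng)
    kd = np.arange(ng, dtype=np.float64)
    k_sum = (ii + jj).astype(np.int64)
    p_sum = np.bincount(k_sum.ravel(), weights=P.ravel(), minlength=2 * ng + 1)[2:]

    autoc = float(np.sum(ii * jj * P))
    da = float(np.sum(kd * p_diff))
    contrast = float(np.sum((ii - jj) ** 2 * P))
    if sx2 > 0 and sy2 > 0:
        corr = (autoc - ux * uy) / np.sqrt(sx2 * sy2)
    else:
        corr = 1.0

    hx = _entropy2(px)
    hy = _entropy2(py)
    hxy = _entropy2(P.ravel())
    outer = np.outer(px, py)
    nz = (P > 0) & (outer > 0)
    hxy1 = float(-np.sum(P[nz] * np.log2(outer[nz])))
    onz = outer > 0
    hxy2 = float(-np.sum(outer[onz] * np.log2(outer[onz])))
    imc1 = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    # MCC: second largest eigenvalue of Q(i,j) = sum_k P(i,k) P(j,k) / (px(i) py(k))
    if ng > 1:
        with np.errstate(divide="ignore", invalid="ignore"):
            W = np.where(py > 0, P / py, 0.0)  # P(j,k)/py(k)
            Q = (P @ W.T) / np.where(px > 0, px, 1.0)[:, None]
        ev = np.linalg.eigvals(Q)
        ev = np.sort(np.abs(ev))
        mcc = float(np.sqrt(max(0.0, ev[-2].real if ev.size > 1 else 1.0)))
    else:
        mcc = 1.0

    off = ~np.eye(ng, dtype=bool)
    inv_var = float(np.sum(P[off] / (ii - jj)[off] ** 2)) if ng > 1 else 0.0

    return {
        "Autocorrelation": autoc,
        "ClusterProminence": float(np.sum((ii + jj - ux - uy) ** 4 * P)),
        "ClusterShade": float(np.sum((ii + jj - ux - uy) ** 3 * P)),
        "ClusterTendency": float(np.sum((ii + jj - ux - uy) ** 2 * P)),
        "Contrast": contrast,
        "Correlation": float(corr),
        "DifferenceAverage": da,
        "DifferenceEntropy": _entropy2(p_diff),
        "DifferenceVariance": float(np.sum((kd - da) ** 2 * p_diff)),
        "Id": float(np.sum(P / (1.0 + np.abs(ii - jj)))),
        "Idm": float(np.sum(P / (1.0 + (ii - jj) ** 2))),
        "Idmn": float(np.sum(P / (1.0 + ((ii - jj) ** 2) / ng**2))),
        "Idn": float(np.sum(P / (1.0 + np.abs(ii - jj) / ng))),
        "Imc1": float(imc1),
        "Imc2": imc2,
        "InverseVariance": inv_var,
        "JointAverage": ux,
        "JointEnergy": float(np.sum(P**2)),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": float(P.max()),
        "SumEntropy": _entropy2(p_sum),
    }


def glcm_features(glcm: np.ndarray) -> dict[str, float]:
    """Average the 22 per-direction features over directions with pairs."""
    per_dir = [
        _glcm_one(glcm[:, :, a])
        for a in range(glcm.shape[2])
        if glcm[:, :, a].sum() > 0
    ]
    if not per_dir:
        raise ValueError("no direction has voxel pairs (ROI too small)")
    return {k: float(np.mean([d[k] for d in per_dir])) for k in per_dir[0]}


# ---------------------------------------------------------------- GLRLM


def _rl_one(R: np.ndarray, n_voxels: int) -> dict[str, float]:
    nr = R.sum()
    i = np.arange(1, R.shape[0] + 1, dtype=np.float64)[:, None]
    l = np.arange(1, R.shape[1] + 1, dtype=np.float64)[None, :]
    p = R / nr
    mu_i = float(np.sum(p * i))
    mu_l = float(np.sum(p * l))
    return {
        "GrayLevelNonUniformity": float(np.sum(R.sum(axis=1) ** 2) / nr),
        "GrayLevelNonUniformityNormalized": float(np.sum(R.sum(axis=1) ** 2) / nr**2),
        "GrayLevelVariance": float(np.sum(p * (i - mu_i) ** 2)),
        "HighGrayLevelRunEmphasis": float(np.sum(R * i**2) / nr),
        "LongRunEmphasis": float(np.sum(R * l**2) / nr),
        "LongRunHighGrayLevelEmphasis": float(np.sum(R * i**2 * l**2) / nr),
        "LongRunLowGrayLevelEmphasis": float(np.sum(R * l**2 / i**2) / nr),
        "LowGrayLevelRunEmphasis": float(np.sum(R / i**2) / nr),
        "RunEntropy": _entropy2(p.ravel()),
        "RunLengthNonUniformity": float(np.sum(R.sum(axis=0) ** 2) / nr),
        "RunLengthNonUniformityNormalized": float(np.sum(R.sum(axis=0) ** 2) / nr**2),
        "RunPercentage": float(nr / n_voxels),
        "RunVariance": float(np.sum(p * (l - mu_l) ** 2)),
        "ShortRunEmphasis": float(np.sum(R / l**2) / nr),
        "ShortRunHighGrayLevelEmphasis": float(np.sum(R * i**2 / l**2) / nr),
        "ShortRunLowGrayLevelEmphasis": float(np.sum(R / (i**2 * l**2)) / nr),
    }


def glrlm_features(glrlm: np.ndarray, n_voxels: int) -> dict[str, float]:
    per_dir = [
        _rl_one(glrlm[:, :, a], n_voxels)
        for a in range(glrlm.shape[2])
        if glrlm[:, :, a].sum() > 0
    ]
    if not per_dir:
        raise ValueError("empty run-length matrix")
    return {k: float(np.mean([d[k] for d in per_dir])) for k in per_dir[0]}


# ---------------------------------------------------------------- GLSZM


def glszm_features(Z: np.ndarray, n_voxels: int) -> dict[str, float]:
    nz = Z.sum()
    if nz == 0:
        raise ValueError("empty size-zone matrix")
    i = np.arange(1, Z.shape[0] + 1, dtype=np.float64)[:, None]
    s = np.arange(1, Z.shape[1] + 1, dtype=np.float64)[None, :]
    p = Z / nz
    mu_i = float(np.sum(p * i))
    mu_s = float(np.sum(p * s))
    return {
        "GrayLevelNonUniformity": float(np.sum(Z.sum(axis=1) ** 2) / nz),
        "GrayLevelNonUniformityNormalized": float(np.sum(Z.sum(axis=1) ** 2) / nz**2),
        "GrayLevelVariance": float(np.sum(p * (i - mu_i) ** 2)),
        "HighGrayLevelZoneEmphasis": float(np.sum(Z * i**2) / nz),
        "LargeAreaEmphasis": float(np.sum(Z * s**2) / nz),
        "LargeAreaHighGrayLevelEmphasis": float(np.sum(Z * i**2 * s**2) / nz),
        "LargeAreaLowGrayLevelEmphasis": float(np.sum(Z * s**2 / i**2) / nz),
        "LowGrayLevelZoneEmphasis": float(np.sum(Z / i**2) / nz),
        "SizeZoneNonUniformity": float(np.sum(Z.sum(axis=0) ** 2) / nz),
        "SizeZoneNonUniformityNormalized": float(np.sum(Z.sum(axis=0) ** 2) / nz**2),
        "SmallAreaEmphasis": float(np.sum(Z / s**2) / nz),
        "SmallAreaHighGrayLevelEmphasis": float(np.sum(Z * i**2 / s**2) / nz),
        "SmallAreaLowGrayLevelEmphasis": float(np.sum(Z / (i**2 * s**2)) / nz),
        "ZoneEntropy": _entropy2(p.ravel()),
        "ZonePercentage": float(nz / n_voxels),
        "ZoneVariance": float(np.sum(p * (s - mu_s) ** 2)),
    }


# ---------------------------------------------------------------- GLDM


def gldm_features(D: np.ndarray) -> dict[str, float]:
    nd = D.sum()
    if nd == 0:
        raise ValueError("empty dependence matrix")
    i = np.arange(1, D.shape[0] + 1, dtype=np.float64)[:, None]
    j = np.arange(1, D.shape[1] + 1, dtype=np.float64)[None, :]
    p = D / nd
    mu_i = float(np.sum(p * i))
    mu_j = float(np.sum(p * j))
    return {
        "DependenceEntropy": _entropy2(p.ravel()),
        "DependenceNonUniformity": float(np.sum(D.sum(axis=0) ** 2) / nd),
        "DependenceNonUniformityNormalized": float(np.sum(D.sum(axis=0) ** 2) / nd**2),
        "DependenceVariance": float(np.sum(p * (j - mu_j) ** 2)),
        "GrayLevelNonUniformity": float(np.sum(D.sum(axis=1) ** 2) / nd),
        "GrayLevelVariance": float(np.sum(p * (i - mu_i) ** 2)),
        "HighGrayLevelEmphasis": float(np.sum(D * i**2) / nd),
        "LargeDependenceEmphasis": float(np.sum(D * j**2) / nd),
        "LargeDependenceHighGrayLevelEmphasis": float(np.sum(D * i**2 * j**2) / nd),
        "LargeDependenceLowGrayLevelEmphasis": float(np.sum(D * j**2 / i**2) / nd),
        "LowGrayLevelEmphasis": float(np.sum(D / i**2) / nd),
        "SmallDependenceEmphasis": float(np.sum(D / j**2) / nd),
        "SmallDependenceHighGrayLevelEmphasis": float(np.sum(D * i**2 / j**2) / nd),
        "SmallDependenceLowGrayLevelEmphasis": float(np.sum(D / (i**2 * j**2)) / nd),
    }


# ---------------------------------------------------------------- NGTDM


def ngtdm_features(n_i: np.ndarray, s_i: np.ndarray) -> dict[str, float]:
    nvp = n_i.sum()
    if nvp == 0:
        raise ValueError("empty neighborhood gray-tone difference matrix")
    p_i = n_i / nvp
    present = p_i > 0
    ngp = int(present.sum())
    i = np.arange(1, len(n_i) + 1, dtype=np.float64)

    denom = float(np.sum(p_i * s_i))
    coarseness = 1.0 / denom if denom > 0 else _COARSENESS_CAP

    if ngp > 1:
        pij = np.outer(p_i, p_i)
        d2 = (i[:, None] - i[None, :]) ** 2
        contrast = float(np.sum(pij * d2) / (ngp * (ngp - 1)) * (s_i.sum() / nvp))
    else:
        contrast = 0.0

    ipi = i * p_i
    busy_den = float(
        np.sum(np.abs(ipi[present][:, None] - ipi[present][None, :]))
    )
    busyness = denom / busy_den if busy_den > 0 else 0.0

    if ngp > 0:
        pi_p = p_i[present]
        si_p = s_i[present]
        i_p = i[present]
        num = (
            np.abs(i_p[:, None] - i_p[None, :])
            * (pi_p[:, None] * si_p[:, None] + pi_p[None, :] * si_p[None, :])
            / (pi_p[:, None] + pi_p[None, :])
        )
        complexity = float(num.sum() / nvp)
        strength_num = float(
            np.sum(
                (pi_p[:, None] + pi_p[None, :]) * (i_p[:, None] - i_p[None, :]) ** 2
            )
        )
        s_tot = float(s_i.sum())
        strength = strength_num / s_tot if s_tot > 0 else 0.0
    else:  # pragma: no cover
        complexity, strength = 0.0, 0.0

    return {
        "Busyness": busyness,
        "Coarseness": min(coarseness, _COARSENESS_CAP),
        "Complexity": complexity,
        "Contrast": contrast,
        "Strength": strength,
    }
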