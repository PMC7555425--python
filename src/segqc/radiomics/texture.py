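"""Texture matrices (GLCM, GLRLM, GLSZM, GLDM, NGTDM) and their features.

All matrices are built on the fixed-bin-width gray-level labels (1..Ng).
GLCM and GLRLM are computed separately along each of the 13 unique
directions of the 26-neighbourhood at distance 1; their features are the
mean of the 13 per-direction values. GLSZM zones and GLDM dependencies use
the full 26-neighbourhood; the GLDM similarity tolerance is 0 (equal gray
level) and the dependence size counts the centre voxel, so it ranges from
1 to 27. Features of an empty matrix (e.g. a single-voxel ROI with no
voxel pairs) are 0 by convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

_EPS = np.spacing(1.0)

#: the 13 unique offsets of the 26-neighbourhood (first nonzero component +1)
DIRECTIONS: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0),
    (0, 1, 0),
    (0, 0, 1),
    (1, 1, 0),
    (1, -1, 0),
    (1, 0, 1),
    (1, 0, -1),
    (0, 1, 1),
    (0, 1, -1),
    (1, 1, 1),
    (1, 1, -1),
    (1, -1, 1),
    (1, -1, -1),
)

ALL_OFFSETS_26 = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
)

GLCM_FEATURES = (
    "Autocorrelation",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "Id",
    "Idm",
    "Idmn",
    "Idn",
    "Imc1",
    "Imc2",
    "InverseVariance",
    "JointAverage",
    "JointEnergy",
    "JointEntropy",
    "MCC",
    "MaximumProbability",
    "SumAverage",
    "SumEntropy",
    "SumSquares",
)

GLRLM_FEATURES = (
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance",
    "HighGrayLevelRunEmphasis",
    "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis",
    "RunEntropy",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "RunVariance",
    "ShortRunEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
)

GLSZM_FEATURES = (
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance",
    "HighGrayLevelZoneEmphasis",
    "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy",
    "ZonePercentage",
    "ZoneVariance",
)

GLDM_FEATURES = (
    "DependenceEntropy",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "DependenceVariance",
    "GrayLevelNonUniformity",
    "GrayLevelVariance",
    "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
)

NGTDM_FEATURES = (
    "Busyness",
    "Coarseness",
    "Complexity",
    "Contrast",
    "Strength",
)


@dataclass(frozen=True)
class TextureMatrices:
    """Raw (unnormalized count) texture matrices for one ROI.

    ``glcm``/``glrlm`` are per-direction lists of 13 matrices; ``glszm``
    columns are zone sizes, ``gldm`` columns dependence sizes (1..27).
    ``n_voxels`` is the in-mask voxel count.
    """

    glcm: list[np.ndarray]
    glrlm: list[np.ndarray]
    glszm: np.ndarray
    gldm: np.ndarray
    ngtdm_p: np.ndarray
    ngtdm_s: np.ndarray
    n_voxels: int
    n_gray: int


def _offset_slices(offset):
    src, dst = [], []
    for o in offset:
        if o > 0:
            src.append(slice(None, -o))
            dst.append(slice(o, None))
        elif o < 0:
            src.append(slice(-o, None))
            dst.append(slice(None, o))
        else:
            src.append(slice(None))
            dst.append(slice(None))
    return tuple(src), tuple(dst)


def glcm_matrices(labels: np.ndarray, ng: int) -> list[np.ndarray]:
    """Symmetric co-occurrence counts at distance 1 per direction."""
    out = []
    for d in DIRECTIONS:
        src, dst = _offset_slices(d)
        a = labels[src]
        b = labels[dst]
        ok = (a > 0) & (b > 0)
        p = np.zeros((ng, ng), dtype=np.float64)
        if ok.any():
            np.add.at(p, (a[ok] - 1, b[ok] - 1), 1.0)
            p = p + p.T
        out.append(p)
    return out


def glrlm_matrices(labels: np.ndarray, mask: np.ndarray, ng: int) -> list[np.ndarray]:
    """Run-length counts per direction.

    Voxels on the same line along direction ``d`` share the base point
    ``p - t d`` where ``t`` is the coordinate along d's first nonzero axis;
    runs are maximal stretches of consecutive ``t`` with equal gray level.
    """
    coords = np.argwhere(mask)
    g = labels[mask]
    max_len = max(labels.shape)
    out = []
    for d in DIRECTIONS:
        dv = np.array(d)
        ax = int(np.flatnonzero(dv)[0])
        t = coords[:, ax]
        base = coords - t[:, None] * dv
        order = np.lexsort((t, base[:, 2], base[:, 1], base[:, 0]))
        bs = base[order]
        ts = t[order]
        gs = g[order]
        new_run = np.ones(len(gs), dtype=bool)
        if len(gs) > 1:
            same_line = np.all(bs[1:] == bs[:-1], axis=1) & (np.diff(ts) == 1)
            new_run[1:] = ~(same_line & (gs[1:] == gs[:-1]))
        starts = np.flatnonzero(new_run)
        lengths = np.diff(np.append(starts, len(gs)))
        r = np.zeros((ng, max_len), dtype=np.float64)
        np.add.at(r, (gs[starts] - 1, lengths - 1), 1.0)
        out.append(r[:, : max(int(lengths.max()), 1)] if len(lengths) else r[:, :1])
    return out


def glszm_matrix(labels: np.ndarray, mask: np.ndarray, ng: int) -> np.ndarray:
    """Zone-size counts: 26-connected components of equal gray level."""
    structure = np.ones((3, 3, 3), dtype=bool)
    sizes_per_level = []
    max_size = 1
    for level in range(1, ng + 1):
        comp, ncomp = ndimage.label(labels == level, structure=structure)
        if ncomp:
            sizes = np.bincount(comp.ravel())[1:]
            sizes_per_level.append((level, sizes))
            max_size = max(max_size, int(sizes.max()))
    s = np.zeros((ng, max_size), dtype=np.float64)
    for level, sizes in sizes_per_level:
        np.add.at(s, (level - 1, sizes - 1), 1.0)
    return s


def gldm_matrix(labels: np.ndarray, mask: np.ndarray, ng: int) -> np.ndarray:
    """Dependence counts: for each voxel, 1 + number of equal-gray
    26-neighbours inside the mask (the centre voxel counts itself)."""
    dep = np.zeros(labels.shape, dtype=np.int64)
    for off in ALL_OFFSETS_26:
        src, dst = _offset_slices(off)
        contrib = np.zeros(labels.shape, dtype=np.int64)
        contrib[dst] = ((labels[src] == labels[dst]) & (labels[src] > 0)).astype(np.int64)
        dep += contrib
    dep_in = dep[mask] + 1
    g = labels[mask]
    d_mat = np.zeros((ng, 27), dtype=np.float64)
    np.add.at(d_mat, (g - 1, dep_in - 1), 1.0)
    return d_mat[:, : int(dep_in.max())]


def ngtdm_vectors(
    labels: np.ndarray, mask: np.ndarray, ng: int
) -> tuple[np.ndarray, np.ndarray, int]:
    """NGTDM probability and gray-tone-difference-sum vectors.

    Only voxels with at least one in-mask 26-neighbour participate.
    Returns (p_i, s_i, N) with vectors indexed by gray level 1..Ng.
    """
    nb_sum = np.zeros(labels.shape, dtype=np.float64)
    nb_cnt = np.zeros(labels.shape, dtype=np.float64)
    inmask = labels > 0
    for off in ALL_OFFSETS_26:
        src, dst = _offset_slices(off)
        add_sum = np.zeros(labels.shape)
        add_cnt = np.zeros(labels.shape)
        add_sum[dst] = np.where(inmask[src], labels[src], 0)
        add_cnt[dst] = inmask[src].astype(float)
        nb_sum += add_sum
        nb_cnt += add_cnt
    valid = inmask & (nb_cnt > 0)
    g = labels[valid].astype(float)
    mean_nb = nb_sum[valid] / nb_cnt[valid]
    diffs = np.abs(g - mean_nb)
    n = int(valid.sum())
    n_i = np.zeros(ng)
    s_i = np.zeros(ng)
    gi = labels[valid] - 1
    np.add.at(n_i, gi, 1.0)
    np.add.at(s_i, gi, diffs)
    p_i = n_i / n if n else n_i
    return p_i, s_i, n


def build_matrices(labels: np.ndarray, mask: np.ndarray, ng: int) -> TextureMatrices:
    p_i, s_i, _ = ngtdm_vectors(labels, mask, ng)
    return TextureMatrices(
        glcm=glcm_matrices(labels, ng),
        glrlm=glrlm_matrices(labels, mask, ng),
        glszm=glszm_matrix(labels, mask, ng),
        gldm=gldm_matrix(labels, mask, ng),
        ngtdm_p=p_i,
        ngtdm_s=s_i,
        n_voxels=int(mask.sum()),
        n_gray=ng,
    )


# ---------------------------------------------------------------------------
# feature computations


def glcm_features_single(counts: np.ndarray) -> dict[str, float]:
    """The 24 GLCM features of one direction's (unnormalized) matrix."""
    total = counts.sum()
    if total == 0:
        return {k: 0.0 for k in GLCM_FEATURES}
    p = counts / total
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    ux = float((i * px).sum())
    uy = float((i * py).sum())
    sigx = float(np.sqrt((px * (i - ux) ** 2).sum()))
    sigy = float(np.sqrt((py * (i - uy) ** 2).sum()))

    k_sum = np.arange(2, 2 * ng + 1, dtype=float)
    p_sum = np.array([p[(ii + jj) == k].sum() for k in k_sum])
    k_diff = np.arange(0, ng, dtype=float)
    p_diff = np.array([p[np.abs(ii - jj) == k].sum() for k in k_diff])

    autocorr = float((p * ii * jj).sum())
    contrast = float((p * (ii - jj) ** 2).sum())
    if sigx > 0 and sigy > 0:
        correlation = (autocorr - ux * uy) / (sigx * sigy)
    else:
        correlation = 1.0
    da = float((k_diff * p_diff).sum())
    dvar = float(((k_diff - da) ** 2 * p_diff).sum())
    dent = float(-(p_diff * np.log2(p_diff + _EPS)).sum())

    hx = float(-(px * np.log2(px + _EPS)).sum())
    hy = float(-(py * np.log2(py + _EPS)).sum())
    pxy = np.outer(px, py)
    hxy = float(-(p * np.log2(p + _EPS)).sum())
    hxy1 = float(-(p * np.log2(pxy + _EPS)).sum())
    hxy2 = float(-(pxy * np.log2(pxy + _EPS)).sum())
    imc1 = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = float(np.sqrt(max(1.0 - np.exp(-2.0 * (hxy2 - hxy)), 0.0)))

    nz = px > 0
    if nz.sum() > 1:
        # Q(i,j) = sum_k p(i,k) p(j,k) / (px(i) py(k))
        psub = p[nz][:, nz]
        q = np.einsum("ik,jk->ij", psub / px[nz, None], psub / py[None, nz])
        eig = np.sort(np.real(np.linalg.eigvals(q)))
        mcc = float(np.sqrt(max(eig[-2], 0.0))) if len(eig) > 1 else 1.0
    else:
        mcc = 1.0

    inv_var = float((p_diff[1:] / k_diff[1:] ** 2).sum()) if ng > 1 else 0.0

    return {
        "Autocorrelation": autocorr,
        "ClusterProminence": float((p * (ii + jj - ux - uy) ** 4).sum()),
        "ClusterShade": float((p * (ii + jj - ux - uy) ** 3).sum()),
        "ClusterTendency": float((p * (ii + jj - ux - uy) ** 2).sum()),
        "Contrast": contrast,
        "Correlation": float(correlation),
        "DifferenceAverage": da,
        "DifferenceEntropy": dent,
        "DifferenceVariance": dvar,
        "Id": float((p_diff / (1.0 + k_diff)).sum()),
        "Idm": float((p_diff / (1.0 + k_diff**2)).sum()),
        "Idmn": float((p_diff / (1.0 + (k_diff / ng) ** 2)).sum()),
        "Idn": float((p_diff / (1.0 + k_diff / ng)).sum()),
        "Imc1": float(imc1),
        "Imc2": imc2,
        "InverseVariance": inv_var,
        "JointAverage": ux,
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": float(p.max()),
        "SumAverage": float((k_sum * p_sum).sum()),
        "SumEntropy": float(-(p_sum * np.log2(p_sum + _EPS)).sum()),
        "SumSquares": float((p * (ii - ux) ** 2).sum()),
    }


def _sre_family(counts: np.ndarray, n_voxels: int, prefix: str) -> dict[str, float]:
    """Shared run-length / size-zone / dependence feature formulas.

    ``counts[i, j]`` is the number of runs/zones/dependencies of gray level
    i+1 and size j+1. Returns the generic feature values keyed by an
    internal name; callers map them onto their class's public names.
    """
    total = counts.sum()
    if total == 0:
        return {}
    ng, ns = counts.shape
    i = np.arange(1, ng + 1, dtype=float)
    j = np.arange(1, ns + 1, dtype=float)
    pg = counts.sum(axis=1)  # per gray level
    ps = counts.sum(axis=0)  # per size
    p = counts / total
    mu_i = float((p.sum(axis=1) * i).sum())
    mu_j = float((p.sum(axis=0) * j).sum())
    pnz = p[p > 0]
    return {
        "small": float((counts / j[None, :] ** 2).sum() / total),
        "large": float((counts * j[None, :] ** 2).sum() / total),
        "gln": float((pg**2).sum() / total),
        "glnn": float((pg**2).sum() / total**2),
        "sn": float((ps**2).sum() / total),
        "snn": float((ps**2).sum() / total**2),
        "percentage": float(total / n_voxels),
        "glv": float((p.sum(axis=1) * (i - mu_i) ** 2).sum()),
        "sv": float((p.sum(axis=0) * (j - mu_j) ** 2).sum()),
        "entropy": float(-(pnz * np.log2(pnz)).sum()),
        "lgl": float((counts / i[:, None] ** 2).sum() / total),
        "hgl": float((counts * i[:, None] ** 2).sum() / total),
        "small_lgl": float((counts / (i[:, None] ** 2 * j[None, :] ** 2)).sum() / total),
        "small_hgl": float((counts * i[:, None] ** 2 / j[None, :] ** 2).sum() / total),
        "large_lgl": float((counts * j[None, :] ** 2 / i[:, None] ** 2).sum() / total),
        "large_hgl": float((counts * (i[:, None] * j[None, :]) ** 2).sum() / total),
    }


_GLRLM_MAP = {
    "GrayLevelNonUniformity": "gln",
    "GrayLevelNonUniformityNormalized": "glnn",
    "GrayLevelVariance": "glv",
    "HighGrayLevelRunEmphasis": "hgl",
    "LongRunEmphasis": "large",
    "LongRunHighGrayLevelEmphasis": "large_hgl",
    "LongRunLowGrayLevelEmphasis": "large_lgl",
    "LowGrayLevelRunEmphasis": "lgl",
    "RunEntropy": "entropy",
    "RunLengthNonUniformity": "sn",
    "RunLengthNonUniformityNormalized": "snn",
    "RunPercentage": "percentage",
    "RunVariance": "sv",
    "ShortRunEmphasis": "small",
    "ShortRunHighGrayLevelEmphasis": "small_hgl",
    "ShortRunLowGrayLevelEmphasis": "small_lgl",
}

_GLSZM_MAP = {
    "GrayLevelNonUniformity": "gln",
    "GrayLevelNonUniformityNormalized": "glnn",
    "GrayLevelVariance": "glv",
    "HighGrayLevelZoneEmphasis": "hgl",
    "LargeAreaEmphasis": "large",
    "LargeAreaHighGrayLevelEmphasis": "large_hgl",
    "LargeAreaLowGrayLevelEmphasis": "large_lgl",
    "LowGrayLevelZoneEmphasis": "lgl",
    "SizeZoneNonUniformity": "sn",
    "SizeZoneNonUniformityNormalized": "snn",
    "SmallAreaEmphasis": "small",
    "SmallAreaHighGrayLevelEmphasis": "small_hgl",
    "SmallAreaLowGrayLevelEmphasis": "small_lgl",
    "ZoneEntropy": "entropy",
    "ZonePercentage": "percentage",
    "ZoneVariance": "sv",
}

_GLDM_MAP = {
    "DependenceEntropy": "entropy",
    "DependenceNonUniformity": "sn",
    "DependenceNonUniformityNormalized": "snn",
    "DependenceVariance": "sv",
    "GrayLevelNonUniformity": "gln",
    "GrayLevelVariance": "glv",
    "HighGrayLevelEmphasis": "hgl",
    "LargeDependenceEmphasis": "large",
    "LargeDependenceHighGrayLevelEmphasis": "large_hgl",
    "LargeDependenceLowGrayLevelEmphasis": "large_lgl",
    "LowGrayLevelEmphasis": "lgl",
    "SmallDependenceEmphasis": "small",
    "SmallDependenceHighGrayLevelEmphasis": "small_hgl",
    "SmallDependenceLowGrayLevelEmphasis": "small_lgl",
}


def _mapped(counts, n_voxels, mapping) -> dict[str, float]:
    generic = _sre_family(counts, n_voxels, "")
    if not generic:
        return {k: 0.0 for k in mapping}
    return {public: generic[internal] for public, internal in mapping.items()}


def glrlm_features_single(counts: np.ndarray, n_voxels: int) -> dict[str, float]:
    return _mapped(counts, n_voxels, _GLRLM_MAP)


def glszm_features(counts: np.ndarray, n_voxels: int) -> dict[str, float]:
    return _mapped(counts, n_voxels, _GLSZM_MAP)


def gldm_features(counts: np.ndarray, n_voxels: int) -> dict[str, float]:
    return _mapped(counts, n_voxels, _GLDM_MAP)


def ngtdm_features(p_i: np.ndarray, s_i: np.ndarray, n_voxels: int) -> dict[str, float]:
    present = p_i > 0
    if n_voxels == 0 or not present.any():
        return {k: 0.0 for k in NGTDM_FEATURES}
    i = np.arange(1, len(p_i) + 1, dtype=float)[present]
    p = p_i[present]
    s = s_i[present]
    ngp = len(p)
    ps = float((p * s).sum())
    coarseness = 1.0 / ps if ps > 0 else 1e6
    if ngp > 1:
        dij2 = (i[:, None] - i[None, :]) ** 2
        contrast = float(
            (p[:, None] * p[None, :] * dij2).sum() / (ngp * (ngp - 1))
        ) * float(s_i.sum() / n_voxels)
        ipi = i * p
        denom = float(np.abs(ipi[:, None] - ipi[None, :]).sum())
        busyness = ps / denom if denom > 0 else 0.0
        absdiff = np.abs(i[:, None] - i[None, :])
        pspair = p[:, None] * s[:, None] + p[None, :] * s[None, :]
        complexity = float(
            (absdiff * pspair / (p[:, None] + p[None, :])).sum() / n_voxels
        )
        strength_num = float(((p[:, None] + p[None, :]) * dij2).sum())
        strength = strength_num / float(s_i.sum()) if s_i.sum() > 0 else 0.0
    else:
        contrast, busyness, complexity, strength = 0.0, 0.0, 0.0, 0.0
    return {
        "Busyness": busyness,
        "Coarseness": coarseness,
        "Complexity": complexity,
        "Contrast": contrast,
        "Strength": strength,
    }


def _direction_average(per_dir: list[dict[str, float]], names) -> dict[str, float]:
    return {
        k: float(np.mean([d[k] for d in per_dir])) for k in names
    }


def compute_features(m: TextureMatrices) -> dict[str, float]:
    """All 75 texture features, keyed ``class_FeatureName``."""
    out: dict[str, float] = {}
    glcm_per_dir = [glcm_features_single(c) for c in m.glcm]
    for k, v in _direction_average(glcm_per_dir, GLCM_FEATURES).items():
        out[f"glcm_{k}"] = v
    glrlm_per_dir = [glrlm_features_single(c, m.n_voxels) for c in m.glrlm]
    for k, v in _direction_average(glrlm_per_dir, GLRLM_FEATURES).items():
        out[f"glrlm_{k}"] = v
    for k, v in glszm_features(m.glszm, m.n_voxels).items():
        out[f"glszm_{k}"] = v
    for k, v in gldm_features(m.gldm, m.n_voxels).items():
        out[f"gldm_{k}"] = v
    for k, v in ngtdm_features(m.ngtdm_p, m.ngtdm_s, m.n_voxels).items():
        out[f"ngtdm_{k}"] = v
    return out
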