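"""Gray-level texture descriptors for mammographic image classification.

Five descriptor families are computed per image and concatenated into a
single 88-dimensional feature vector:

==========  =====  =========================================================
family      count  description
==========  =====  =========================================================
GLCM        22     Haralick/Soh/Clausi statistics of the gray-level
                   co-occurrence matrix, averaged over the four distance-1
                   directions (0, 45, 90, 135 degrees)
LBGLCM      22     the same statistics computed on the LBP-coded image
GLRLM       7      Galloway/Chu run-length statistics, averaged over the
                   four directions
LBP         10     rotation-invariant uniform histogram of 8-neighbor local
                   binary pattern codes
SFTA        27     segmentation-based fractal texture analysis: multi-level
                   Otsu decomposition into 2*nt-1 binary images (nt=5), each
                   contributing border fractal dimension, mean gray level
                   and foreground size
==========  =====  =========================================================

All descriptors operate on quantized nonnegative integer images.  The
coordinate convention is row-major with origin at the top-left and 0-based
indices; gray-level indices inside the GLCM/GLRLM statistics are 1-based
(the classical convention, which keeps 1/i^2-style terms finite).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("mammotex")

DEFAULT_QUANT_LEVELS = 32
#: (row-shift, col-shift) displacement for each co-occurrence direction.
DIRECTION_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

GLCM_FEATURE_NAMES = (
    "autocorrelation",
    "contrast",
    "correlation",
    "cluster_prominence",
    "cluster_shade",
    "cluster_tendency",
    "dissimilarity",
    "energy",
    "entropy",
    "homogeneity",
    "inverse_difference_moment",
    "maximum_probability",
    "sum_of_squares_variance",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "imc2",
    "inverse_difference_normalized",
    "inverse_difference_moment_normalized",
)

GLRLM_FEATURE_NAMES = ("sre", "lre", "gln", "rln", "rp", "lgre", "hgre")

LBP_BIN_NAMES = tuple(f"u{k}" for k in range(9)) + ("nonuniform",)


class DegenerateImageError(ValueError):
    """Image lacks the gray-level diversity an operation requires."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GrayImage:
    """A 2-D nonnegative integer intensity matrix with a known level count.

    ``n_levels`` is the number of representable gray levels: every pixel lies
    in ``[0, n_levels - 1]``.  For raw 8-bit input it is 256 regardless of
    image content, so quantization does not depend on the brightest pixel
    present.
    """

    pixels: np.ndarray
    n_levels: int

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError(f"image must be 2-D and nonempty, got shape {px.shape}")
        if not np.issubdtype(px.dtype, np.integer):
            raise ValueError(f"pixel dtype must be integer, got {px.dtype}")
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if px.min() < 0 or px.max() >= self.n_levels:
            raise ValueError(
                f"pixel values must lie in [0, {self.n_levels - 1}], "
                f"got [{px.min()}, {px.max()}]"
            )
        object.__setattr__(self, "pixels", px)

    @classmethod
    def from_array(cls, arr, n_levels: int | None = None) -> "GrayImage":
        """Wrap an array, inferring the level count from dtype if omitted."""
        arr = np.asarray(arr)
        if n_levels is None:
            if arr.dtype == np.uint8:
                n_levels = 256
            elif arr.dtype == np.uint16:
                n_levels = 65536
            else:
                n_levels = int(arr.max()) + 1 if arr.size else 2
            n_levels = max(n_levels, 2)
        return cls(arr.astype(np.int64), n_levels)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class CooccurrenceMatrix:
    """Counts of pixel-value pairs at a fixed displacement."""

    counts: np.ndarray
    offset: tuple[int, int]
    normalized: bool
    symmetric: bool

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("co-occurrence matrix must be square")
        if (c < 0).any():
            raise ValueError("co-occurrence counts must be nonnegative")
        object.__setattr__(self, "counts", c)

    @property
    def n_levels(self) -> int:
        return self.counts.shape[0]


@dataclass(frozen=True)
class RunLengthMatrix:
    """P(i, j): number of maximal runs of gray level i with length j.

    ``counts[i, j-1]`` holds P(i, j); run lengths are 1-based.
    """

    counts: np.ndarray
    direction: int
    n_runs: int
    n_pixels: int

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 2:
            raise ValueError("run-length matrix must be 2-D")
        if (c < 0).any():
            raise ValueError("run counts must be nonnegative")
        object.__setattr__(self, "counts", c)


@dataclass(frozen=True)
class SftaDecomposition:
    """Binary decomposition of an image by multi-level Otsu thresholds."""

    thresholds: np.ndarray
    pair_set: tuple[tuple[int, int], ...]
    upper_set: tuple[tuple[int, int], ...]
    binary_images: tuple[np.ndarray, ...]


@dataclass(frozen=True)
class FeatureVector:
    """A named, fixed-order real feature vector for one image."""

    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or len(v) != len(self.names):
            raise ValueError("values and names must have equal length")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class FeatureConfig:
    """Default configuration reproducing the 88-feature layout."""

    quant_levels: int = DEFAULT_QUANT_LEVELS
    directions: tuple[int, ...] = (0, 45, 90, 135)
    lbp_points: int = 8
    lbp_radius: int = 1
    sfta_nt: int = 5
    sfta_levels: int = 256  # histogram resolution for the Otsu search
    descriptors: tuple[str, ...] = ("glcm", "lbglcm", "glrlm", "lbp", "sfta")


# ---------------------------------------------------------------------------
# Quantization
# ---------------------------------------------------------------------------


def quantize(image: GrayImage, n_levels: int) -> GrayImage:
    """Requantize to ``n_levels`` gray levels.

    Output value = floor(pixel * n_levels / input_levels); the mapping is
    monotone and maps the input endpoints onto 0 and n_levels - 1.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    out = (image.pixels.astype(np.int64) * n_levels) // image.n_levels
    return GrayImage(out, n_levels)


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------


def glcm(
    image: GrayImage,
    offset: tuple[int, int],
    symmetric: bool = True,
    normalized: bool = True,
) -> CooccurrenceMatrix:
    """Co-occurrence counts of pixel pairs (p, p + offset).

    ``counts[i, j]`` = number of positions p where pixel(p) = i and
    pixel(p + offset) = j.  Symmetric mode adds the transposed counts;
    normalized mode divides by the total so entries sum to 1.
    """
    dr, dc = offset
    rows, cols = image.shape
    if rows < 2 or cols < 2:
        raise ValueError(f"co-occurrence needs at least a 2x2 image, got {image.shape}")
    if dr == 0 and dc == 0:
        raise ValueError("offset must be nonzero")
    if abs(dr) >= rows or abs(dc) >= cols:
        raise ValueError(f"offset {offset} exceeds image dimensions {image.shape}")

    n = image.n_levels
    src = image.pixels[
        max(0, -dr) : rows - max(0, dr), max(0, -dc) : cols - max(0, dc)
    ]
    dst = image.pixels[
        max(0, dr) : rows - max(0, -dr), max(0, dc) : cols - max(0, -dc)
    ]
    pairs = src.ravel() * n + dst.ravel()
    counts = np.bincount(pairs, minlength=n * n).reshape(n, n).astype(float)
    if symmetric:
        counts = counts + counts.T
    if normalized:
        total = counts.sum()
        if total > 0:
            counts = counts / total
    return CooccurrenceMatrix(counts, (dr, dc), normalized, symmetric)


def _entropy(p: np.ndarray, base2: bool = True) -> float:
    """Shannon entropy with the 0*log(0) := 0 convention."""
    p = p[p > 0]
    if p.size == 0:
        return 0.0
    logs = np.log2(p) if base2 else np.log(p)
    return float(-(p * logs).sum())


def glcm_features(m: CooccurrenceMatrix) -> np.ndarray:
    """The 22 canonical co-occurrence statistics of a normalized GLCM.

    Names and formulas are listed in :data:`GLCM_FEATURE_NAMES` and the
    package documentation.  Entropies use log base 2 (the information
    measures of correlation use natural logs internally, as in the classical
    definitions).  Statistics whose denominator degenerates (zero marginal
    variance, zero marginal entropy) are defined as 0 so constant images
    yield finite vectors.
    """
    if not m.normalized:
        raise ValueError("glcm_features requires a normalized matrix")
    P = m.counts
    N = m.n_levels
    idx = np.arange(1, N + 1, dtype=float)  # 1-based gray index
    I = idx[:, None]
    J = idx[None, :]

    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float((idx * px).sum())
    mu_y = float((idx * py).sum())
    sd_x = float(np.sqrt(((idx - mu_x) ** 2 * px).sum()))
    sd_y = float(np.sqrt(((idx - mu_y) ** 2 * py).sum()))

    # marginal distributions of i+j (range 2..2N) and |i-j| (range 0..N-1)
    ks = np.arange(2, 2 * N + 1, dtype=float)
    p_sum = np.zeros(2 * N - 1)
    kd = np.arange(0, N, dtype=float)
    p_diff = np.zeros(N)
    iplusj = (I + J).astype(int)
    iminusj = np.abs(I - J).astype(int)
    np.add.at(p_sum, (iplusj - 2).ravel(), P.ravel())
    np.add.at(p_diff, iminusj.ravel(), P.ravel())

    autocorrelation = float((I * J * P).sum())
    contrast = float(((I - J) ** 2 * P).sum())
    if sd_x * sd_y > 1e-12:
        correlation = (autocorrelation - mu_x * mu_y) / (sd_x * sd_y)
    else:
        correlation = 0.0
    cp_base = I + J - mu_x - mu_y
    cluster_prominence = float((cp_base**4 * P).sum())
    cluster_shade = float((cp_base**3 * P).sum())
    cluster_tendency = float((cp_base**2 * P).sum())
    dissimilarity = float((np.abs(I - J) * P).sum())
    energy = float((P**2).sum())
    entropy = _entropy(P.ravel())
    homogeneity = float((P / (1.0 + np.abs(I - J))).sum())
    inv_diff_moment = float((P / (1.0 + (I - J) ** 2)).sum())
    maximum_probability = float(P.max())
    sos_variance = float(((I - mu_x) ** 2 * P).sum())
    sum_average = float((ks * p_sum).sum())
    sum_variance = float(((ks - sum_average) ** 2 * p_sum).sum())
    sum_entropy = _entropy(p_sum)
    mu_d = float((kd * p_diff).sum())
    difference_variance = float(((kd - mu_d) ** 2 * p_diff).sum())
    difference_entropy = _entropy(p_diff)

    # information measures of correlation (natural logs, classical form)
    hxy = _entropy(P.ravel(), base2=False)
    pxy = px[:, None] * py[None, :]
    mask = (P > 0) & (pxy > 0)
    hxy1 = float(-(P[mask] * np.log(pxy[mask])).sum())
    mask2 = pxy > 0
    hxy2 = float(-(pxy[mask2] * np.log(pxy[mask2])).sum())
    hx = _entropy(px, base2=False)
    hy = _entropy(py, base2=False)
    denom = max(hx, hy)
    imc1 = (hxy - hxy1) / denom if denom > 1e-12 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    inv_diff_norm = float((P / (1.0 + np.abs(I - J) / N)).sum())
    inv_diff_moment_norm = float((P / (1.0 + ((I - J) / N) ** 2)).sum())

    return np.array(
        [
            autocorrelation,
            contrast,
            correlation,
            cluster_prominence,
            cluster_shade,
            cluster_tendency,
            dissimilarity,
            energy,
            entropy,
            homogeneity,
            inv_diff_moment,
            maximum_probability,
            sos_variance,
            sum_average,
            sum_variance,
            sum_entropy,
            difference_variance,
            difference_entropy,
            imc1,
            imc2,
            inv_diff_norm,
            inv_diff_moment_norm,
        ]
    )


def glcm_features_averaged(
    image: GrayImage,
    directions: tuple[int, ...] = (0, 45, 90, 135),
    symmetric: bool = True,
) -> np.ndarray:
    """22 GLCM statistics averaged over co-occurrence directions."""
    feats = [
        glcm_features(glcm(image, DIRECTION_OFFSETS[d], symmetric, True))
        for d in directions
    ]
    return np.mean(feats, axis=0)


# ---------------------------------------------------------------------------
# LBP
# ---------------------------------------------------------------------------

# (row, col) neighbor offsets ordered counterclockwise starting east;
# bit p carries weight 2**p.
_LBP_OFFSETS = (
    (0, 1),
    (-1, 1),
    (-1, 0),
    (-1, -1),
    (0, -1),
    (1, -1),
    (1, 0),
    (1, 1),
)


def lbp_image(image: GrayImage, P: int = 8, R: int = 1) -> GrayImage:
    """8-neighbor local binary pattern codes of the interior pixels.

    Each interior pixel receives code sum_p s(g_p - g_c) * 2**p with
    s(x) = 1 iff x >= 0 (ties count as 1).  Border pixels are excluded, so
    the code image is smaller than the input by 2R per side.
    """
    if P != 8 or R != 1:
        raise NotImplementedError("only the default P=8, R=1 configuration is supported")
    rows, cols = image.shape
    if rows < 2 * R + 1 or cols < 2 * R + 1:
        raise ValueError(f"image {image.shape} too small for R={R} neighborhood")
    a = image.pixels
    center = a[1:-1, 1:-1]
    code = np.zeros_like(center)
    for p, (dr, dc) in enumerate(_LBP_OFFSETS):
        neigh = a[1 + dr : rows - 1 + dr, 1 + dc : cols - 1 + dc]
        code = code + ((neigh >= center).astype(np.int64) << p)
    return GrayImage(code, 256)


def _uniform_bin_table() -> np.ndarray:
    """Map each 8-bit code to its rotation-invariant uniform histogram bin.

    Uniform codes (at most 2 circular 0/1 transitions) map to their set-bit
    count 0..8; all others map to bin 9.
    """
    table = np.empty(256, dtype=np.int64)
    for code in range(256):
        rotated = ((code << 1) | (code >> 7)) & 0xFF
        transitions = bin(code ^ rotated).count("1")
        table[code] = bin(code).count("1") if transitions <= 2 else 9
    return table


_LBP_UNIFORM_BINS = _uniform_bin_table()


def lbp_histogram(codes: GrayImage) -> np.ndarray:
    """Normalized 10-bin rotation-invariant uniform LBP histogram."""
    bins = _LBP_UNIFORM_BINS[codes.pixels.ravel()]
    hist = np.bincount(bins, minlength=10).astype(float)
    total = hist.sum()
    return hist / total if total > 0 else hist


def lbglcm_features(
    image: GrayImage,
    quant_levels: int = DEFAULT_QUANT_LEVELS,
    directions: tuple[int, ...] = (0, 45, 90, 135),
) -> np.ndarray:
    """GLCM statistics of the LBP-coded image.

    Pure composition: LBP codes (0..255) are requantized to ``quant_levels``
    and fed through the standard co-occurrence statistics.
    """
    codes = lbp_image(image)
    return glcm_features_averaged(quantize(codes, quant_levels), directions)


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------


def _direction_lines(a: np.ndarray, direction: int) -> list[np.ndarray]:
    rows, cols = a.shape
    if direction == 0:
        return [a[r] for r in range(rows)]
    if direction == 90:
        return [a[:, c] for c in range(cols)]
    if direction == 135:  # down-right diagonals
        return [a.diagonal(k) for k in range(-rows + 1, cols)]
    if direction == 45:  # up-right anti-diagonals
        f = np.flipud(a)
        return [f.diagonal(k) for k in range(-rows + 1, cols)]
    raise ValueError(f"direction must be one of 0, 45, 90, 135; got {direction}")


def glrlm(image: GrayImage, direction: int) -> RunLengthMatrix:
    """Run-length matrix: maximal equal-value runs along one direction."""
    a = image.pixels
    max_run = max(a.shape)
    counts = np.zeros((image.n_levels, max_run), dtype=np.int64)
    n_runs = 0
    for line in _direction_lines(a, direction):
        if line.size == 0:
            continue
        boundaries = np.flatnonzero(np.diff(line) != 0)
        starts = np.concatenate(([0], boundaries + 1))
        ends = np.concatenate((boundaries, [line.size - 1]))
        lengths = ends - starts + 1
        values = line[starts]
        np.add.at(counts, (values, lengths - 1), 1)
        n_runs += len(starts)
    return RunLengthMatrix(counts, direction, n_runs, a.size)


def glrlm_features(rlm: RunLengthMatrix) -> np.ndarray:
    """The 7 classical run-length statistics (Galloway/Chu forms).

    SRE, LRE, GLN, RLN, RP, LGRE, HGRE with the gray index i counted from 1
    and all sums normalized by the total run count n (RP by the pixel count).
    """
    P = rlm.counts.astype(float)
    n = rlm.n_runs
    if n == 0:
        raise ValueError("run-length matrix has no runs")
    j = np.arange(1, P.shape[1] + 1, dtype=float)[None, :]
    i = np.arange(1, P.shape[0] + 1, dtype=float)[:, None]
    sre = float((P / j**2).sum() / n)
    lre = float((j**2 * P).sum() / n)
    gln = float((P.sum(axis=1) ** 2).sum() / n)
    rln = float((P.sum(axis=0) ** 2).sum() / n)
    rp = n / rlm.n_pixels
    lgre = float((P / i**2).sum() / n)
    hgre = float((i**2 * P).sum() / n)
    return np.array([sre, lre, gln, rln, rp, lgre, hgre])


def glrlm_features_averaged(
    image: GrayImage, directions: tuple[int, ...] = (0, 45, 90, 135)
) -> np.ndarray:
    return np.mean([glrlm_features(glrlm(image, d)) for d in directions], axis=0)


# ---------------------------------------------------------------------------
# Multi-level Otsu
# ---------------------------------------------------------------------------


def otsu_multilevel(image: GrayImage, nt: int) -> np.ndarray:
    """``nt`` thresholds maximizing between-class variance of the histogram.

    Exact dynamic programming over the gray-level histogram: the image is
    partitioned into nt+1 contiguous intensity classes minimizing the total
    within-class weighted sum of squares (equivalent to maximizing
    between-class variance).  Returned thresholds are the upper gray value
    of each class except the last; a pixel v belongs to the class with
    t_{k-1} < v <= t_k.  Deterministic: ties resolve to the smallest
    threshold vector.
    """
    if nt < 1:
        raise ValueError("nt must be >= 1")
    hist = np.bincount(image.pixels.ravel(), minlength=image.n_levels).astype(float)
    present = np.flatnonzero(hist)
    if len(present) <= nt:
        raise DegenerateImageError(
            f"need more than {nt} distinct gray levels, found {len(present)}"
        )
    # compress to occupied bins only; a DP segment boundary is always at an
    # occupied bin, so this loses nothing and bounds the cost at O(nt*L^2)
    w = hist[present]
    v = present.astype(float)
    L = len(present)
    cw = np.concatenate(([0.0], np.cumsum(w)))
    cwv = np.concatenate(([0.0], np.cumsum(w * v)))
    cwv2 = np.concatenate(([0.0], np.cumsum(w * v * v)))

    def seg_cost(a: np.ndarray, b: int) -> np.ndarray:
        """Within-class SS of bins a..b (vectorized over start index a)."""
        W = cw[b + 1] - cw[a]
        S = cwv[b + 1] - cwv[a]
        S2 = cwv2[b + 1] - cwv2[a]
        with np.errstate(invalid="ignore", divide="ignore"):
            cost = S2 - np.where(W > 0, S * S / np.maximum(W, 1e-300), 0.0)
        return cost

    n_seg = nt + 1
    INF = np.inf
    # dp[k][b] = min cost of splitting bins 0..b into k+1 segments
    dp = np.full((n_seg, L), INF)
    arg = np.zeros((n_seg, L), dtype=np.int64)
    starts = np.arange(L)
    for b in range(L):
        dp[0, b] = seg_cost(np.array([0]), b)[0]
    for k in range(1, n_seg):
        for b in range(k, L):
            a = starts[k : b + 1]  # segment k starts at bin a
            total = dp[k - 1, a - 1] + seg_cost(a, b)
            best = int(np.argmin(total))  # first (smallest) argmin on ties
            dp[k, b] = total[best]
            arg[k, b] = a[best]
    # backtrack: threshold k = value of the last bin in segment k
    thresholds = np.empty(nt, dtype=np.int64)
    b = L - 1
    for k in range(n_seg - 1, 0, -1):
        a = arg[k, b]
        thresholds[k - 1] = int(present[a - 1])
        b = a - 1
    return thresholds


# ---------------------------------------------------------------------------
# Box counting and SFTA
# ---------------------------------------------------------------------------


def box_counting_dimension(border: np.ndarray) -> float:
    """Box-counting fractal dimension of a binary pixel set.

    Dyadic box sizes {1, 2, 4, ..., min(dim)/2} anchored at the (0, 0)
    corner; the dimension is the least-squares slope of log(occupied boxes)
    against log(1/box size).  Empty sets (and degenerate size ranges) give 0.
    """
    border = np.asarray(border, dtype=bool)
    if not border.any():
        return 0.0
    sizes = []
    s = 1
    while s <= min(border.shape) // 2:
        sizes.append(s)
        s *= 2
    if len(sizes) < 2:
        return 0.0
    counts = []
    for s in sizes:
        rows, cols = border.shape
        pr = (-rows) % s
        pc = (-cols) % s
        padded = np.pad(border, ((0, pr), (0, pc)))
        blocks = padded.reshape(padded.shape[0] // s, s, padded.shape[1] // s, s)
        counts.append(int(blocks.any(axis=(1, 3)).sum()))
    log_inv_s = -np.log(np.array(sizes, dtype=float))
    log_n = np.log(np.array(counts, dtype=float))
    slope = np.polyfit(log_inv_s, log_n, 1)[0]
    return float(slope)


def region_border(binary: np.ndarray) -> np.ndarray:
    """Border pixels: foreground with at least one background 4-neighbor.

    Only in-image neighbors count, so a region flush against the image edge
    has no border there (a half-plane's border is a straight line).
    """
    b = np.asarray(binary, dtype=bool)
    padded = np.pad(b, 1, mode="edge")
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    return b & ~interior


def sfta_decompose(image: GrayImage, nt: int) -> SftaDecomposition:
    """Threshold sets TA (contiguous pairs) and TB (upper thresholds)."""
    t = otsu_multilevel(image, nt)
    max_gray = image.n_levels - 1
    pair_set = tuple((int(t[i]), int(t[i + 1])) for i in range(nt - 1))
    upper_set = tuple((int(ti), max_gray) for ti in t)
    px = image.pixels
    binaries = [ (px > lo) & (px <= hi) for lo, hi in pair_set ]
    binaries += [ px > ti for ti in t ]
    return SftaDecomposition(t, pair_set, upper_set, tuple(binaries))


def sfta(image: GrayImage, nt: int = 5) -> np.ndarray:
    """Segmentation-based fractal texture analysis feature vector.

    2*nt - 1 binary images (nt - 1 two-threshold bands, then nt upper
    threshold images, both in ascending threshold order), each contributing
    (border fractal dimension, mean gray level of the foreground, foreground
    pixel count).  An empty binary image contributes (0, 0, 0).
    """
    if nt < 2:
        raise ValueError("nt must be >= 2")
    decomp = sfta_decompose(image, nt)
    px = image.pixels
    feats = []
    for b in decomp.binary_images:
        if b.any():
            frac = box_counting_dimension(region_border(b))
            mean_gray = float(px[b].mean())
            size = int(b.sum())
        else:
            frac, mean_gray, size = 0.0, 0.0, 0
        feats.extend([frac, mean_gray, float(size)])
    return np.array(feats)


# ---------------------------------------------------------------------------
# Full 88-feature assembly
# ---------------------------------------------------------------------------


def _sfta_block(image: GrayImage, config: FeatureConfig) -> np.ndarray:
    img = image
    if img.n_levels > config.sfta_levels:
        img = quantize(img, config.sfta_levels)
    try:
        return sfta(img, config.sfta_nt)
    except DegenerateImageError:
        logger.warning(
            "image has too few distinct levels for %d-threshold SFTA; "
            "emitting zeros for the SFTA block",
            config.sfta_nt,
        )
        return np.zeros(3 * (2 * config.sfta_nt - 1))


def feature_names(config: FeatureConfig = FeatureConfig()) -> tuple[str, ...]:
    """Descriptor-qualified names in extraction order."""
    names: list[str] = []
    for d in config.descriptors:
        if d in ("glcm", "lbglcm"):
            names += [f"{d}.{n}" for n in GLCM_FEATURE_NAMES]
        elif d == "glrlm":
            names += [f"glrlm.{n}" for n in GLRLM_FEATURE_NAMES]
        elif d == "lbp":
            names += [f"lbp.{n}" for n in LBP_BIN_NAMES]
        elif d == "sfta":
            nb = 2 * config.sfta_nt - 1
            for k in range(nb):
                names += [
                    f"sfta.b{k}.fractal_dim",
                    f"sfta.b{k}.mean_gray",
                    f"sfta.b{k}.size",
                ]
        else:
            raise ValueError(f"unknown descriptor {d!r}")
    return tuple(names)


def extract_features(
    image: GrayImage, config: FeatureConfig = FeatureConfig()
) -> FeatureVector:
    """Concatenated texture descriptor vector for one image.

    Default layout [GLCM 22 | LBGLCM 22 | GLRLM 7 | LBP 10 | SFTA 27] = 88.
    GLCM, LBGLCM and GLRLM statistics are averaged over the four distance-1
    directions; deterministic for a fixed image and config.
    """
    q = quantize(image, config.quant_levels)
    blocks: dict[str, np.ndarray] = {}
    for d in config.descriptors:
        if d == "glcm":
            blocks[d] = glcm_features_averaged(q, config.directions)
        elif d == "lbglcm":
            blocks[d] = lbglcm_features(image, config.quant_levels, config.directions)
        elif d == "glrlm":
            blocks[d] = glrlm_features_averaged(q, config.directions)
        elif d == "lbp":
            blocks[d] = lbp_histogram(lbp_image(image, config.lbp_points, config.lbp_radius))
        elif d == "sfta":
            blocks[d] = _sfta_block(image, config)
        else:
            raise ValueError(f"unknown descriptor {d!r}")
    values = np.concatenate([blocks[d] for d in config.descriptors])
    return FeatureVector(values, feature_names(config))
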