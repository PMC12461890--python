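"""Independent brute-force oracles used to validate the filter implementations.

Everything here is written as plainly as possible — explicit kernels,
double loops, reflect padding by hand — so it shares no code path with the
package's separable / FFT implementations.
"""

from __future__ import annotations

import numpy as np


def reflect_pad(channel: np.ndarray, radius: int) -> np.ndarray:
    """Reflect padding without repeating the edge sample (scipy 'reflect')."""
    return np.pad(channel, radius, mode="symmetric")


def naive_convolve(channel: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Direct double-loop 2-D correlation-style convolution, reflect boundary.

    The kernels used in this suite are all symmetric under point reflection,
    so convolution and correlation coincide.
    """
    kh, kw = kernel.shape
    rh, rw = kh // 2, kw // 2
    padded = np.pad(channel, ((rh, rh), (rw, rw)), mode="symmetric")
    h, w = channel.shape
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            acc = 0.0
            for a in range(kh):
                for b in range(kw):
                    acc += kernel[a, b] * padded[i + a, j + b]
            out[i, j] = acc
    return out


def gaussian_kernel_1d(sigma: float, order: int = 0, truncate: float = 4.0) -> np.ndarray:
    """Sampled Gaussian (or its exact derivative) on integer offsets.

    Mirrors the standard construction: the 0th-order kernel is the sampled
    Gaussian normalised to unit sum; derivative orders apply the Hermite
    recurrence to those normalised weights.
    """
    radius = int(truncate * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=float)
    phi = np.exp(-0.5 * (x / sigma) ** 2)
    phi /= phi.sum()
    if order == 0:
        return phi
    # q(x) with d/dx [q phi] = [q' - (x/sigma^2) q] phi, applied `order` times
    q = np.array([1.0])
    for _ in range(order):
        qd = np.polynomial.polynomial.polyder(q)
        qx = np.polynomial.polynomial.polymul([0.0, -1.0 / sigma**2], q)
        out = np.zeros(max(len(qd), len(qx)))
        out[: len(qd)] += qd
        out[: len(qx)] += qx
        q = out
    return np.polynomial.polynomial.polyval(x, q) * phi


def gaussian_kernel_2d(sigma: float, order: tuple[int, int] = (0, 0)) -> np.ndarray:
    """Separable 2-D Gaussian-derivative kernel as an explicit outer product."""
    k_r = gaussian_kernel_1d(sigma, order[0])
    k_c = gaussian_kernel_1d(sigma, order[1])
    return np.outer(k_r, k_c)


def naive_gaussian_blur(channel: np.ndarray, sigma: float) -> np.ndarray:
    return naive_convolve(channel, gaussian_kernel_2d(sigma))


SOBEL_ROW = np.array([[-1, -2, -1], [0, 0, 0], [1, 2, 1]], dtype=float)
SOBEL_COL = SOBEL_ROW.T


def naive_sobel_magnitude(channel: np.ndarray, sigma: float) -> np.ndarray:
    smoothed = naive_gaussian_blur(channel, sigma) if sigma > 0 else channel
    gr = naive_convolve(smoothed, SOBEL_ROW)
    gc = naive_convolve(smoothed, SOBEL_COL)
    return np.sqrt(gr**2 + gc**2)


def naive_hessian_eigenvalues(
    channel: np.ndarray, sigma: float
) -> tuple[np.ndarray, np.ndarray]:
    hrr = naive_convolve(channel, gaussian_kernel_2d(sigma, (2, 0)))
    hcc = naive_convolve(channel, gaussian_kernel_2d(sigma, (0, 2)))
    hrc = naive_convolve(channel, gaussian_kernel_2d(sigma, (1, 1)))
    large = np.empty_like(hrr)
    small = np.empty_like(hrr)
    for i in range(hrr.shape[0]):
        for j in range(hrr.shape[1]):
            m = np.array([[hrr[i, j], hrc[i, j]], [hrc[i, j], hcc[i, j]]])
            ev = np.linalg.eigvalsh(m)
            small[i, j], large[i, j] = ev[0], ev[1]
    return large, small


def naive_membrane_responses(
    channel: np.ndarray, kernels: np.ndarray
) -> np.ndarray:
    return np.stack([naive_convolve(channel, k) for k in kernels])


def anova_ss_oracle(values: np.ndarray, geno: np.ndarray, rater: np.ndarray):
    """Balanced two-way sums of squares from explicit group-mean formulas."""
    grand = values.mean()
    genotypes = np.unique(geno)
    raters = np.unique(rater)
    n_cell = len(values) / (len(genotypes) * len(raters))
    ss_a = sum(
        (values[geno == g].mean() - grand) ** 2 * (values[geno == g]).size
        for g in genotypes
    )
    ss_b = sum(
        (values[rater == r].mean() - grand) ** 2 * (values[rater == r]).size
        for r in raters
    )
    ss_cells = 0.0
    ss_resid = 0.0
    for g in genotypes:
        for r in raters:
            cell = values[(geno == g) & (rater == r)]
            ss_cells += cell.size * (cell.mean() - grand) ** 2
            ss_resid += ((cell - cell.mean()) ** 2).sum()
    ss_ab = ss_cells - ss_a - ss_b
    ss_total = ((values - grand) ** 2).sum()
    df_a = len(genotypes) - 1
    df_b = len(raters) - 1
    df_ab = df_a * df_b
    df_resid = len(values) - len(genotypes) * len(raters)
    return {
        "ss": (ss_a, ss_b, ss_ab, ss_resid, ss_total),
        "df": (df_a, df_b, df_ab, df_resid),
        "F": (
            (ss_a / df_a) / (ss_resid / df_resid),
            (ss_b / df_b) / (ss_resid / df_resid),
            (ss_ab / df_ab) / (ss_resid / df_resid),
        ),
        "n_cell": n_cell,
    }


def pearson_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook covariance-formula Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum()))
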