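"""Independent brute-force oracles used to cross-check the implementation.

Every function here is a deliberately naive double-loop evaluation of the
defining formulas, sharing no code with the package.  They are O(M·N·w²)
and meant for tiny fixtures only.
"""

import numpy as np


def pad_sym(a: np.ndarray, r: int) -> np.ndarray:
    return np.pad(a, r, mode="symmetric")


def box_mean_loop(a: np.ndarray, r: int) -> np.ndarray:
    """Window mean with symmetric reflection, one window at a time."""
    p = pad_sym(a, r)
    out = np.empty_like(a, dtype=np.float64)
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            out[i, j] = p[i : i + 2 * r + 1, j : j + 2 * r + 1].mean()
    return out


def box_std_loop(a: np.ndarray, r: int) -> np.ndarray:
    """Window population standard deviation (divide by window size)."""
    p = pad_sym(a, r)
    out = np.empty_like(a, dtype=np.float64)
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            w = p[i : i + 2 * r + 1, j : j + 2 * r + 1]
            out[i, j] = np.sqrt(np.maximum(np.mean(w * w) - np.mean(w) ** 2, 0.0))
    return out


def edge_weight_loop(G: np.ndarray, radius: int, eps: float):
    """Direct evaluation of chi, Gamma and the sigmoid edge factor."""
    chi = box_std_loop(G, 1) * box_std_loop(G, radius)
    n = G.size
    Gamma = np.empty_like(chi)
    flat = chi.ravel()
    for i in range(chi.shape[0]):
        for j in range(chi.shape[1]):
            Gamma[i, j] = np.mean((chi[i, j] + eps) / (flat + eps))
    mu = chi.mean()
    spread = mu - chi.min()
    if spread <= 0:
        gamma = np.zeros_like(chi)
    else:
        eta = 4.0 / spread
        gamma = 1.0 - 1.0 / (1.0 + np.exp(eta * (chi - mu)))
    return chi, Gamma, gamma


def gdgf_loop(X: np.ndarray, G: np.ndarray, radius: int, lam: float, eps: float,
              weight_mode: str = "multiply"):
    """Window-by-window linear regression of X on G with the edge-aware
    penalty, then per-pixel averaging of the window coefficients."""
    chi, Gamma, gamma = edge_weight_loop(G, radius, eps)
    r = radius
    mu_G = box_mean_loop(G, r)
    mu_X = box_mean_loop(X, r)
    mu_GX = box_mean_loop(G * X, r)
    var_G = box_mean_loop(G * G, r) - mu_G * mu_G
    reg = lam * Gamma if weight_mode == "multiply" else lam / Gamma
    a = (mu_GX - mu_G * mu_X + reg * gamma) / (var_G + reg)
    b = mu_X - a * mu_G
    return box_mean_loop(a, r) * G + box_mean_loop(b, r), a, b


def average_gradient_loop(f: np.ndarray) -> float:
    M, N = f.shape
    total = 0.0
    for i in range(M - 1):
        for j in range(N - 1):
            total += np.sqrt((f[i, j] - f[i + 1, j]) ** 2 + (f[i, j] - f[i, j + 1]) ** 2)
    return total / ((M - 1) * (N - 1))


def entropy_loop(px: np.ndarray, n_bins: int = 256) -> float:
    counts = np.zeros(n_bins)
    for v in px.ravel():
        counts[min(int(v * n_bins), n_bins - 1)] += 1
    p = counts / counts.sum()
    return float(-sum(pi * np.log2(pi) for pi in p if pi > 0))


def spatial_frequency_loop(f: np.ndarray) -> float:
    M, N = f.shape
    rf = sum((f[i, j] - f[i, j - 1]) ** 2 for i in range(M) for j in range(1, N)) / (M * N)
    cf = sum((f[i, j] - f[i - 1, j]) ** 2 for i in range(1, M) for j in range(N)) / (M * N)
    return float(np.sqrt(rf + cf))


def edge_intensity_loop(f: np.ndarray) -> float:
    """3×3 convolution (kernel flipped) with the ¼-scaled Sobel templates."""
    gx_k = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float) / 4.0
    gy_k = np.array([[-1, -2, -1], [0, 0, 0], [1, 2, 1]], dtype=float) / 4.0
    p = pad_sym(f, 1)
    M, N = f.shape
    total = 0.0
    for i in range(M):
        for j in range(N):
            gx = gy = 0.0
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    # convolution: kernel index mirrored
                    gx += gx_k[1 - di, 1 - dj] * p[i + 1 + di, j + 1 + dj]
                    gy += gy_k[1 - di, 1 - dj] * p[i + 1 + di, j + 1 + dj]
            total += np.sqrt(gx * gx + gy * gy)
    return total / (M * N)


def agcwd_map_loop(pdf: np.ndarray, alpha: float):
    """Hand evaluation of the weighted distribution, weighted CDF and the
    per-level gamma for a small histogram."""
    pdf = np.asarray(pdf, dtype=float)
    pmin, pmax = pdf.min(), pdf.max()
    if pmax == pmin:
        pdf_w = pdf.copy()
    else:
        pdf_w = pmax * ((pdf - pmin) / (pmax - pmin)) ** alpha
    cdf_w = np.cumsum(pdf_w) / pdf_w.sum()
    gamma = 1.0 - cdf_w
    return pdf_w, cdf_w, gamma
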