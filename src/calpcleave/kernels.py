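"""Sub-kernel families, Gram-matrix construction, normalization and combination.

Four kernel families are supported, each paired with the feature track it
suits best:

* ``linear`` / ``rbf`` — position-dependent kernels over one-hot encoded
  windows (the classic binary encoding for protease-site SVMs);
* ``string`` — a position-dependent kernel counting identical k-mers (all
  lengths 1..d) at matching offsets in two equal-length windows;
* ``spectrum`` — a position-independent gapped-substring kernel: the inner
  product of occurrence-count vectors over all patterns of length <= d' with
  up to g interior wildcard positions.  Its positional looseness suits the
  flexible secondary-structure and accessibility tracks.

An 'X' (unknown residue) never matches in the string/spectrum kernels and
encodes as an all-zero block for linear/rbf, so terminal padding cannot
create spurious similarity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from itertools import combinations

import numpy as np
import scipy.sparse as sp

from .data_model import Instance, WindowSpec, binary_encode, recut

KERNEL_KINDS = ("linear", "rbf", "string", "spectrum")
TRACKS = ("sequence", "ss", "sa")


@dataclass(frozen=True)
class KernelConfig:
    """Definition of one sub-kernel: family, feature track, window and
    family-specific parameters (rbf width sigma; string order d; spectrum
    order d' and gap budget g)."""

    kind: str
    track: str = "sequence"
    spec: WindowSpec = field(default_factory=lambda: WindowSpec(5, 5))
    sigma: float = 1.0
    order_d: int = 3
    order_dprime: int = 3
    gaps_g: int = 1
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.kind not in KERNEL_KINDS:
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.track not in TRACKS:
            raise ValueError(f"unknown track {self.track!r}")
        if self.kind == "rbf" and self.sigma <= 0:
            raise ValueError("rbf width sigma must be positive")
        if self.kind == "string" and not (1 <= self.order_d <= self.spec.width):
            raise ValueError("string order d must satisfy 1 <= d <= window length")
        if self.kind == "spectrum" and (self.order_dprime < 1 or self.gaps_g < 0):
            raise ValueError("spectrum requires d' >= 1 and g >= 0")

    def replace(self, **kw) -> "KernelConfig":
        d = asdict(self)
        d["spec"] = self.spec
        d.update(kw)
        return KernelConfig(**d)

    def summary(self) -> str:
        base = f"{self.kind}[{self.track}] win=({self.spec.left},{self.spec.right})"
        if self.kind == "rbf":
            return base + f" sigma={self.sigma:g}"
        if self.kind == "string":
            return base + f" d={self.order_d}"
        if self.kind == "spectrum":
            return base + f" d'={self.order_dprime} g={self.gaps_g}"
        return base

    def to_dict(self) -> dict:
        d = asdict(self)
        d["spec"] = {"left": self.spec.left, "right": self.spec.right}
        return d

    @staticmethod
    def from_dict(d: dict) -> "KernelConfig":
        d = dict(d)
        d["spec"] = WindowSpec(**d["spec"])
        return KernelConfig(**d)


@dataclass
class KernelMatrix:
    """A (normalized) Gram matrix together with the config that produced it."""

    values: np.ndarray
    config: KernelConfig | None = None
    normalized: bool = False
    ids: list[str] | None = None

    @property
    def shape(self):
        return self.values.shape

    def to_tsv(self, path) -> None:
        ids = self.ids or [str(i) for i in range(self.values.shape[0])]
        with open(path, "w") as fh:
            fh.write("\t".join(ids) + "\n")
            for row in self.values:
                fh.write("\t".join(f"{v:.12g}" for v in row) + "\n")

    @staticmethod
    def from_tsv(path) -> "KernelMatrix":
        with open(path) as fh:
            ids = fh.readline().rstrip("\n").split("\t")
            values = np.loadtxt(fh, ndmin=2)
        return KernelMatrix(values=values, ids=ids)


# ---------------------------------------------------------------------------
# Pairwise kernels
# ---------------------------------------------------------------------------

def k_linear(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) != len(y):
        raise ValueError("encoded vectors must have equal length")
    return float(np.dot(x, y))


def k_rbf(x: np.ndarray, y: np.ndarray, sigma: float) -> float:
    """Gaussian RBF: exp(-||x-y||^2 / (2 sigma^2))."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if len(x) != len(y):
        raise ValueError("encoded vectors must have equal length")
    d2 = float(np.sum((np.asarray(x) - np.asarray(y)) ** 2))
    return math.exp(-d2 / (2.0 * sigma * sigma))


def string_features(s: str, order_d: int) -> dict:
    """Position-anchored k-mer features: one binary feature per (offset,
    length, substring) for k = 1..d; substrings containing 'X' are dropped."""
    feats = {}
    L = len(s)
    for k in range(1, min(order_d, L) + 1):
        for i in range(L - k + 1):
            sub = s[i:i + k]
            if "X" not in sub:
                feats[(i, sub)] = 1.0
    return feats


def k_string(s: str, t: str, order_d: int) -> float:
    """Count of identical k-mers (k = 1..d) at matching positions."""
    if len(s) != len(t):
        raise ValueError("string kernel requires equal-length windows")
    fs, ft = string_features(s, order_d), string_features(t, order_d)
    if len(ft) < len(fs):
        fs, ft = ft, fs
    return float(sum(v * ft[k] for k, v in fs.items() if k in ft))


def spectrum_features(s: str, order_dprime: int, gaps_g: int) -> dict:
    """Occurrence counts of gapped patterns of length <= d'.

    A pattern is a contiguous window of length m with up to g interior
    positions replaced by wildcards (never the first or last position;
    patterns of length 1 and 2 have no interior, hence no wildcards).  Each
    wildcard placement is a distinct feature.  Patterns whose literal
    positions touch 'X' are not counted.
    """
    feats: dict = {}
    L = len(s)
    for m in range(1, min(order_dprime, L) + 1):
        interior = range(1, m - 1)
        max_w = min(gaps_g, max(m - 2, 0))
        wildcard_sets = [ws for n_w in range(max_w + 1)
                         for ws in combinations(interior, n_w)]
        for i in range(L - m + 1):
            window = s[i:i + m]
            for ws in wildcard_sets:
                lits = tuple(window[j] for j in range(m) if j not in ws)
                if "X" in lits:
                    continue
                key = (m, ws, lits)
                feats[key] = feats.get(key, 0.0) + 1.0
    return feats


def k_spectrum(s: str, t: str, order_dprime: int, gaps_g: int) -> float:
    """Gapped spectrum kernel: Phi(s) . Phi(t); s and t may differ in length."""
    fs = spectrum_features(s, order_dprime, gaps_g)
    ft = spectrum_features(t, order_dprime, gaps_g)
    if len(ft) < len(fs):
        fs, ft = ft, fs
    return float(sum(v * ft[k] for k, v in fs.items() if k in ft))


def kernel_value(config: KernelConfig, a: Instance, b: Instance,
                 stored: WindowSpec) -> float:
    """Evaluate one sub-kernel on a pair of instances (windows re-cut to the
    config's own spec)."""
    wa = recut(a.window(config.track), stored, config.spec)
    wb = recut(b.window(config.track), stored, config.spec)
    if config.kind == "linear":
        return k_linear(binary_encode(wa, config.track),
                        binary_encode(wb, config.track))
    if config.kind == "rbf":
        return k_rbf(binary_encode(wa, config.track),
                     binary_encode(wb, config.track), config.sigma)
    if config.kind == "string":
        return k_string(wa, wb, config.order_d)
    return k_spectrum(wa, wb, config.order_dprime, config.gaps_g)


# ---------------------------------------------------------------------------
# Gram-matrix construction (vectorized via explicit sparse feature maps)
# ---------------------------------------------------------------------------

def _windows(instances: list[Instance], config: KernelConfig,
             stored: WindowSpec) -> list[str]:
    return [recut(inst.window(config.track), stored, config.spec)
            for inst in instances]


def _sparse_features(windows: list[str], config: KernelConfig,
                     vocab: dict | None = None):
    """Stack per-window feature dicts into a CSR matrix over a shared
    vocabulary (grown in place when shared across train/query)."""
    if vocab is None:
        vocab = {}
    data, indices, indptr = [], [], [0]
    for w in windows:
        if config.kind == "string":
            feats = string_features(w, config.order_d)
        else:
            feats = spectrum_features(w, config.order_dprime, config.gaps_g)
        for key, v in feats.items():
            idx = vocab.setdefault(key, len(vocab))
            indices.append(idx)
            data.append(v)
        indptr.append(len(indices))
    mat = sp.csr_matrix((data, indices, indptr),
                        shape=(len(windows), max(len(vocab), 1)))
    return mat, vocab


def _raw_gram(instances: list[Instance], config: KernelConfig,
              stored: WindowSpec) -> np.ndarray:
    windows = _windows(instances, config, stored)
    if config.kind in ("string", "spectrum"):
        X, _ = _sparse_features(windows, config)
        return np.asarray((X @ X.T).todense(), dtype=float)
    X = np.array([binary_encode(w, config.track) for w in windows])
    G = X @ X.T
    if config.kind == "linear":
        return G
    sq = np.diag(G)
    d2 = sq[:, None] + sq[None, :] - 2.0 * G
    return np.exp(-np.maximum(d2, 0.0) / (2.0 * config.sigma ** 2))


def _raw_cross(train: list[Instance], query: list[Instance],
               config: KernelConfig, stored: WindowSpec):
    """Raw K(train, query) plus the two self-similarity vectors."""
    wt = _windows(train, config, stored)
    wq = _windows(query, config, stored)
    if config.kind in ("string", "spectrum"):
        Xt, vocab = _sparse_features(wt, config)
        Xq, vocab = _sparse_features(wq, config, vocab)
        Xt.resize((Xt.shape[0], len(vocab)))
        K = np.asarray((Xt @ Xq.T).todense(), dtype=float)
        st = np.asarray(Xt.multiply(Xt).sum(axis=1)).ravel()
        sq_ = np.asarray(Xq.multiply(Xq).sum(axis=1)).ravel()
        return K, st, sq_
    Xt = np.array([binary_encode(w, config.track) for w in wt])
    Xq = np.array([binary_encode(w, config.track) for w in wq])
    K = Xt @ Xq.T
    st = np.einsum("ij,ij->i", Xt, Xt)
    sq_ = np.einsum("ij,ij->i", Xq, Xq)
    if config.kind == "rbf":
        d2 = st[:, None] + sq_[None, :] - 2.0 * K
        K = np.exp(-np.maximum(d2, 0.0) / (2.0 * config.sigma ** 2))
        st = np.ones_like(st, dtype=float)
        sq_ = np.ones_like(sq_, dtype=float)
    return K, st, sq_


def build_matrix(instances, config: KernelConfig,
                 stored: WindowSpec | None = None) -> KernelMatrix:
    """Gram matrix of the configured kernel over all instance pairs.

    ``stored`` is the window spec the instances were cut at (defaults to the
    config's own spec); the config's window is re-cut from it.
    """
    insts = list(instances)
    stored = stored or getattr(instances, "spec", None) or config.spec
    K = _raw_gram(insts, config, stored)
    km = KernelMatrix(values=K, config=config, normalized=False,
                      ids=[f"{i.source_id}:{i.bond_index}" for i in insts])
    return normalize(km) if config.normalize else km


def kernel_between(train, query, config: KernelConfig,
                   stored: WindowSpec) -> np.ndarray:
    """K(train, query) under a config, cosine-normalized if the config says so."""
    K, st, sq_ = _raw_cross(list(train), list(query), config, stored)
    if config.normalize:
        denom = np.sqrt(np.outer(st, sq_))
        with np.errstate(divide="ignore", invalid="ignore"):
            K = np.where(denom > 0, K / np.where(denom > 0, denom, 1.0), 0.0)
    return K


def normalize(K: KernelMatrix) -> KernelMatrix:
    """Cosine normalization K'(i,j) = K(i,j)/sqrt(K(i,i) K(j,j)).

    Rows with zero self-similarity get diagonal 1 and off-diagonal 0, keeping
    the matrix positive semi-definite with a unit diagonal.
    """
    V = K.values
    if V.shape[0] != V.shape[1]:
        raise ValueError("normalization requires a square matrix")
    d = np.diag(V).copy()
    zero = d <= 0
    d[zero] = 1.0
    out = V / np.sqrt(np.outer(d, d))
    out[zero, :] = 0.0
    out[:, zero] = 0.0
    out[np.diag_indices_from(out)] = 1.0
    return KernelMatrix(values=out, config=K.config, normalized=True, ids=K.ids)


def combine(matrices: list[KernelMatrix], betas) -> KernelMatrix:
    """Weighted sum sum_k beta_k K_k of sub-kernel Gram matrices (PSD for
    non-negative weights)."""
    betas = np.asarray(betas, dtype=float)
    if len(matrices) != len(betas):
        raise ValueError("one weight required per matrix")
    if np.any(betas < 0):
        raise ValueError("kernel weights must be non-negative")
    shapes = {m.values.shape for m in matrices}
    if len(shapes) != 1:
        raise ValueError("matrices must share a shape")
    out = np.zeros(matrices[0].values.shape)
    for b, m in zip(betas, matrices):
        out += b * m.values
    return KernelMatrix(values=out, config=None,
                        normalized=all(m.normalized for m in matrices),
                        ids=matrices[0].ids)
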