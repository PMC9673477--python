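"""Quantitative-trait simulation on a genotype matrix under a linear mixed model.

The phenotype of sample *s* is built as

    y = sum_i beta_i x_i  [+ beta_int (x_i o x_j)]  + u + eps,

where ``u = Z gamma`` is a polygenic background over 1,000 randomly chosen
markers with i.i.d. Gaussian effects (sd 0.1 by default), ``eps`` is Gaussian
or mean-centered gamma (skewed) noise whose variance is tied to the background
via the heritability ``h``:

    Var(eps) = (1 - h) / h * Var(u),

and each fixed (causal) effect is scaled so that it explains a target fraction
``c_i`` of the total phenotypic variance.  Multiplicative (epistatic) effects
enter through the Hadamard product of two causal marker columns.

The built-in grid reproduces twelve named configurations (A..L) crossed with
three heritabilities {0.7, 0.85, 0.95}: sample-size series A-D (n=100..2000,
one causal marker at c=0.3), weak/strong multiplicative pairs E/F, weak/strong
skewed-noise rows G/H (gamma shapes 4 and 1), and additive series I-L with
5/20/50/100 causal markers whose fractions are drawn from stated normal laws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .genotypes import GenotypeMatrix

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedPhenotype",
    "sample_background",
    "noise_variance",
    "draw_noise",
    "effect_size",
    "simulate",
    "builtin_configs",
    "realized_variance_components",
    "write_truth_sidecar",
    "read_truth_sidecar",
]

HERITABILITY_GRID = (0.7, 0.85, 0.95)
_MAX_CAUSAL_RETRIES = 100


@dataclass
class SimulationConfig:
    """One simulation setting.

    ``causal_fractions`` fixes the per-effect variance fractions; alternatively
    ``fraction_rule = (mean, sd)`` draws ``n_causal`` fractions from
    Normal(mean, sd^2)/100, redrawing non-positive values.  ``interaction``
    is ``(i, j, c_int)`` over *causal-list positions*, adding the Hadamard
    product of causal markers i and j with target fraction ``c_int``.
    """

    name: str
    n_samples: int
    n_causal: int
    heritability: float
    causal_fractions: list[float] | None = None
    fraction_rule: tuple[float, float] | None = None
    interaction: tuple[int, int, float] | None = None
    noise_family: str = "gaussian"
    gamma_shape: float = 4.0
    n_background: int = 1000
    background_sd: float = 0.1
    seed: int | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.heritability < 1):
            raise ValueError(f"heritability must be in (0,1), got {self.heritability}")
        if self.noise_family not in ("gaussian", "gamma"):
            raise ValueError(f"unknown noise family {self.noise_family!r}")
        if self.n_causal > 0 and (self.causal_fractions is None) == (self.fraction_rule is None):
            raise ValueError("give exactly one of causal_fractions / fraction_rule")
        if self.causal_fractions is not None:
            total = sum(self.causal_fractions)
            if self.interaction is not None:
                total += self.interaction[2]
            if total >= 1:
                raise ValueError(f"target fractions sum to {total} >= 1")


@dataclass
class GroundTruth:
    """Realized parameters of one simulated phenotype."""

    background_indices: np.ndarray  # columns of Z
    gamma: np.ndarray               # background effects
    causal_indices: np.ndarray      # fixed-effect marker columns
    beta: np.ndarray                # fixed effects; interaction coefficient last if present
    interaction: tuple[int, int] | None  # causal-list positions forming the Hadamard term
    u: np.ndarray                   # per-sample polygenic value
    epsilon: np.ndarray             # per-sample noise draw
    sigma2: float                   # noise variance
    sample_indices: np.ndarray      # rows of the source genotype matrix used
    x_fixed: np.ndarray             # n x len(beta) fixed-effect design (interaction col last)


@dataclass
class SimulatedPhenotype:
    y: np.ndarray
    sample_ids: list[str]
    config: SimulationConfig
    truth: GroundTruth
    realized_fractions: dict[str, float] = field(default_factory=dict)


def sample_background(
    G: GenotypeMatrix, n_background: int, sd: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw the polygenic term: marker subset, Gaussian effects, u = Z gamma."""
    if n_background > G.n_markers:
        raise ValueError(f"n_background={n_background} exceeds marker count {G.n_markers}")
    idx = rng.choice(G.n_markers, size=n_background, replace=False)
    gamma = rng.normal(0.0, sd, size=n_background)
    u = G.values[:, idx].astype(np.float64) @ gamma
    return idx, gamma, u


def noise_variance(h: float, var_u: float) -> float:
    """Noise variance that leaves the polygenic term a share ``h`` of Var(u+eps)."""
    if not (0 < h < 1):
        raise ValueError(f"heritability must be in (0,1), got {h}")
    if var_u < 0:
        raise ValueError("var_u must be non-negative")
    return (1.0 - h) / h * var_u


def draw_noise(
    family: str, sigma2: float, gamma_shape: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Mean-centered noise with variance ``sigma2``.

    Gaussian noise is symmetric; gamma noise (shape k, scale sqrt(sigma2/k),
    minus its mean) keeps variance sigma2 while adding skewness 2/sqrt(k).
    """
    if sigma2 <= 0:
        raise ValueError(f"sigma2 must be positive, got {sigma2}")
    if family == "gaussian":
        return rng.normal(0.0, np.sqrt(sigma2), size=n)
    if family == "gamma":
        if gamma_shape <= 0:
            raise ValueError(f"gamma shape must be positive, got {gamma_shape}")
        scale = np.sqrt(sigma2 / gamma_shape)
        return rng.gamma(gamma_shape, scale, size=n) - gamma_shape * scale
    raise ValueError(f"unknown noise family {family!r}")


def effect_size(c: float, var_background_pheno: float, var_x: float) -> float:
    """Fixed-effect coefficient giving variance share ``c`` against the background.

    beta = sqrt((c / (1 - c)) * Var(u + eps) / Var(x)); with several effects the
    caller replaces 1 - c by 1 - sum(c) so every effect keeps its share of the
    *total* variance (see :func:`simulate`).
    """
    if not (0 < c < 1):
        raise ValueError(f"target fraction must be in (0,1), got {c}")
    if var_x <= 0:
        raise ValueError("causal marker has zero variance")
    return float(np.sqrt((c / (1.0 - c)) * var_background_pheno / var_x))


def _effect_sizes_joint(cs: np.ndarray, var_bg: float, var_xs: np.ndarray) -> np.ndarray:
    denom = 1.0 - float(cs.sum())
    if denom <= 0:
        raise ValueError(f"target fractions sum to {cs.sum()} >= 1")
    return np.sqrt((cs / denom) * var_bg / var_xs)


def _draw_fractions(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if config.n_causal == 0:
        return np.empty(0)
    if config.causal_fractions is not None:
        return np.asarray(config.causal_fractions, dtype=float)
    mean, sd = config.fraction_rule
    out = np.empty(config.n_causal)
    for i in range(config.n_causal):
        c = rng.normal(mean, sd) / 100.0
        while c <= 0:  # redraw non-positive fractions (rare under all built-in rules)
            c = rng.normal(mean, sd) / 100.0
        out[i] = c
    return out


def simulate(config: SimulationConfig, G: GenotypeMatrix, seed: int | None = None) -> SimulatedPhenotype:
    """Simulate one phenotype vector on ``G`` under ``config``.

    Fully reproducible from the seed (argument wins over ``config.seed``).
    Causal markers are drawn disjoint from the background set; a causal marker
    (or Hadamard product) that is constant over the sampled rows is redrawn,
    up to a bounded retry count.
    """
    if seed is None:
        seed = config.seed if config.seed is not None else 0
    rng = np.random.default_rng(seed)
    if config.n_samples > G.n_samples:
        raise ValueError(f"config needs {config.n_samples} samples, matrix has {G.n_samples}")

    sample_idx = rng.choice(G.n_samples, size=config.n_samples, replace=False)
    Gs = G.values[sample_idx].astype(np.float64)
    sample_ids = [G.sample_ids[i] for i in sample_idx]

    bg_idx, gamma, u = sample_background(
        G.take_samples(sample_idx), config.n_background, config.background_sd, rng
    )
    var_u = float(np.var(u, ddof=1))
    sigma2 = noise_variance(config.heritability, var_u)
    eps = draw_noise(config.noise_family, sigma2, config.gamma_shape, config.n_samples, rng)
    var_bg = float(np.var(u + eps, ddof=1))

    cs = _draw_fractions(config, rng)
    if config.interaction is not None:
        cs_all = np.append(cs, config.interaction[2])
    else:
        cs_all = cs

    # causal markers: disjoint from the background, non-constant in the sample
    candidates = np.setdiff1d(np.arange(G.n_markers), bg_idx)
    causal_idx = np.empty(config.n_causal, dtype=int)
    cols: list[np.ndarray] = []
    chosen: set[int] = set()
    for i in range(config.n_causal):
        for _ in range(_MAX_CAUSAL_RETRIES):
            j = int(rng.choice(candidates))
            if j in chosen:
                continue
            x = Gs[:, j]
            if np.var(x, ddof=1) > 0:
                causal_idx[i] = j
                chosen.add(j)
                cols.append(x)
                break
        else:
            raise RuntimeError("could not draw a non-constant causal marker")

    if config.interaction is not None:
        i0, j0, _ = config.interaction
        for _ in range(_MAX_CAUSAL_RETRIES):
            x_int = cols[i0] * cols[j0]
            if np.var(x_int, ddof=1) > 0:
                break
            # degenerate product: redraw the second member of the pair
            j = int(rng.choice(candidates))
            if j in chosen or np.var(Gs[:, j], ddof=1) == 0:
                continue
            chosen.discard(causal_idx[j0])
            causal_idx[j0] = j
            chosen.add(j)
            cols[j0] = Gs[:, j]
        else:
            raise RuntimeError("could not form a non-constant Hadamard interaction")
        cols_all = cols + [x_int]
        interaction = (i0, j0)
    else:
        cols_all = cols
        interaction = None

    if cols_all:
        X = np.column_stack(cols_all)
        var_xs = X.var(axis=0, ddof=1)
        beta = _effect_sizes_joint(cs_all, var_bg, var_xs)
        y = X @ beta + u + eps
    else:
        X = np.empty((config.n_samples, 0))
        beta = np.empty(0)
        y = u + eps

    truth = GroundTruth(
        background_indices=bg_idx,
        gamma=gamma,
        causal_indices=causal_idx,
        beta=beta,
        interaction=interaction,
        u=u,
        epsilon=eps,
        sigma2=sigma2,
        sample_indices=sample_idx,
        x_fixed=X,
    )
    sp = SimulatedPhenotype(y=y, sample_ids=sample_ids, config=config, truth=truth)
    sp.realized_fractions = realized_variance_components(sp)
    return sp


def realized_variance_components(sp: SimulatedPhenotype) -> dict[str, float]:
    """Empirical variance share of each fixed effect, the background, and noise.

    Shares are Var(term)/Var(y); they sum to 1 only up to the sample
    covariances between terms (near-orthogonal by construction).
    """
    t = sp.truth
    var_y = float(np.var(sp.y, ddof=1))
    out: dict[str, float] = {}
    n_marginal = len(t.causal_indices)
    for i in range(t.x_fixed.shape[1]):
        term = t.beta[i] * t.x_fixed[:, i]
        key = f"causal_{i}" if i < n_marginal else "interaction"
        out[key] = float(np.var(term, ddof=1)) / var_y
    out["background"] = float(np.var(t.u, ddof=1)) / var_y
    out["noise"] = float(np.var(t.epsilon, ddof=1)) / var_y
    return out


def builtin_configs(heritabilities: tuple[float, ...] = HERITABILITY_GRID) -> list[SimulationConfig]:
    """The twelve named settings crossed with the heritability grid (36 configs)."""
    rows: list[dict] = [
        dict(name="A", label="#100", n_samples=100, n_causal=1, causal_fractions=[0.3]),
        dict(name="B", label="#500", n_samples=500, n_causal=1, causal_fractions=[0.3]),
        dict(name="C", label="#1000", n_samples=1000, n_causal=1, causal_fractions=[0.3]),
        dict(name="D", label="#2000", n_samples=2000, n_causal=1, causal_fractions=[0.3]),
        dict(name="E", label="MultWeak", n_samples=1000, n_causal=2,
             causal_fractions=[0.05, 0.05], interaction=(0, 1, 0.2)),
        dict(name="F", label="MultStrong", n_samples=1000, n_causal=2,
             causal_fractions=[0.01, 0.01], interaction=(0, 1, 0.28)),
        dict(name="G", label="SkewedWeak", n_samples=1000, n_causal=1,
             causal_fractions=[0.3], noise_family="gamma", gamma_shape=4.0),
        dict(name="H", label="SkewedStrong", n_samples=1000, n_causal=1,
             causal_fractions=[0.3], noise_family="gamma", gamma_shape=1.0),
        dict(name="I", label="Add5", n_samples=1000, n_causal=5, fraction_rule=(6.0, 2.0)),
        dict(name="J", label="Add20", n_samples=1000, n_causal=20, fraction_rule=(1.5, 0.5)),
        dict(name="K", label="Add50", n_samples=1000, n_causal=50, fraction_rule=(0.6, 0.2)),
        dict(name="L", label="Add100", n_samples=1000, n_causal=100, fraction_rule=(0.3, 0.1)),
    ]
    configs = []
    for h in heritabilities:
        for row in rows:
            configs.append(SimulationConfig(heritability=h, **row))
    return configs


def get_config(name: str, heritability: float) -> SimulationConfig:
    """Look up one built-in configuration by letter and heritability."""
    for cfg in builtin_configs((heritability,)):
        if cfg.name == name:
            return cfg
    raise KeyError(f"no built-in configuration named {name!r}")


# ---------------------------------------------------------------------------
# sidecar serialization


def write_truth_sidecar(sp: SimulatedPhenotype, path) -> None:
    t = sp.truth
    payload = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(sp.config).items()},
        "background_indices": t.background_indices.tolist(),
        "gamma": t.gamma.tolist(),
        "causal_indices": t.causal_indices.tolist(),
        "beta": t.beta.tolist(),
        "interaction": list(t.interaction) if t.interaction is not None else None,
        "sigma2": t.sigma2,
        "sample_indices": t.sample_indices.tolist(),
        "u": t.u.tolist(),
        "epsilon": t.epsilon.tolist(),
        "realized_fractions": sp.realized_fractions,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def read_truth_sidecar(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)
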