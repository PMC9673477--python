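"""Genotype matrices: synthesis, filtering, encoding, and delimited-table I/O.

The central container is :class:`GenotypeMatrix`, a dense samples x markers
matrix of additive minor-allele counts in {0, 1, 2} with unique sample and
marker identifiers.  The synthetic generator emulates a prepared inbred SNP
panel: fully homozygous calls, minor allele frequency (MAF) constrained to a
band, duplicate-free columns, and optional block-wise linkage disequilibrium
(LD) induced by a shared latent Gaussian factor per block.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeMatrix",
    "EncodedMatrix",
    "GenotypeFormatError",
    "generate_synthetic_genotypes",
    "compute_maf",
    "filter_maf",
    "filter_duplicates",
    "encode",
    "decode_onehot",
    "read_genotype_table",
    "write_genotype_table",
    "read_phenotype_table",
    "write_phenotype_table",
]

ENCODING_SCHEMES = ("additive012", "additive_centered", "onehot")


class GenotypeFormatError(ValueError):
    """Raised for malformed genotype/phenotype tables (names the offending cell)."""


@dataclass
class GenotypeMatrix:
    """Samples x markers additive allele-count matrix.

    Attributes
    ----------
    sample_ids : list of str
        Unique row identifiers.
    marker_ids : list of str
        Unique column identifiers.
    values : ndarray of shape (n_samples, n_markers)
        Integer allele counts in {0, 1, 2}; no missing entries.
    chromosome, position : ndarray or None
        Optional per-marker metadata (1-based positions).
    """

    sample_ids: list[str]
    marker_ids: list[str]
    values: np.ndarray
    chromosome: np.ndarray | None = None
    position: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x markers)")
        n, m = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.marker_ids) != m:
            raise ValueError(f"{len(self.marker_ids)} marker ids for {m} columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.marker_ids)) != m:
            raise ValueError("duplicate marker ids")
        if not np.isin(self.values, (0, 1, 2)).all():
            raise ValueError("genotype values must be in {0, 1, 2} with no missing entries")
        self.values = self.values.astype(np.int8, copy=False)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def take_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        """Row subset (e.g., the simulator's random sample draw)."""
        idx = np.asarray(idx)
        return GenotypeMatrix(
            [self.sample_ids[i] for i in idx],
            list(self.marker_ids),
            self.values[idx],
            self.chromosome,
            self.position,
        )

    def take_markers(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            list(self.sample_ids),
            [self.marker_ids[i] for i in idx],
            self.values[:, idx],
            None if self.chromosome is None else self.chromosome[idx],
            None if self.position is None else self.position[idx],
        )


@dataclass
class EncodedMatrix:
    """Model-facing real-valued view of a :class:`GenotypeMatrix`.

    ``feature_group`` is only set for the one-hot scheme and maps each output
    column to ``(marker_index, genotype_state)`` of its source marker.
    """

    scheme: str
    values: np.ndarray
    marker_ids: list[str]
    feature_group: list[tuple[int, int]] | None = None


def _smallest_maf(n_samples: int, homozygous_only: bool) -> float:
    # one minor homozygote -> 2/(2n); one het -> 1/(2n)
    return (1.0 / n_samples) if homozygous_only else (0.5 / n_samples)


def generate_synthetic_genotypes(
    n_samples: int,
    n_markers: int,
    maf_low: float = 0.10,
    maf_high: float = 0.5,
    homozygous_only: bool = True,
    ld_block_size: int = 0,
    ld_rho: float = 0.0,
    seed: int = 0,
) -> GenotypeMatrix:
    """Generate an inbred-panel-like genotype matrix.

    Each marker draws a target MAF uniformly from ``(maf_low, maf_high]`` and
    realizes genotypes by thresholding a latent Gaussian; markers inside an LD
    block share a latent factor with loading ``sqrt(ld_rho)``, so within-block
    genotype correlation is approximately ``ld_rho`` while blocks stay
    independent.  Markers whose *empirical* MAF falls outside the band, or
    which duplicate an earlier column, are redrawn, so the returned panel
    satisfies the band exactly and is duplicate-free.

    With ``homozygous_only`` (the default, matching a selfing species panel)
    genotypes are in {0, 2}; otherwise the two alleles are drawn separately
    (sharing the block factor) giving {0, 1, 2}.
    """
    if not (0 < maf_low < maf_high <= 0.5):
        raise ValueError(f"require 0 < maf_low < maf_high <= 0.5, got ({maf_low}, {maf_high})")
    if not (0 <= ld_rho < 1):
        raise ValueError(f"ld_rho must be in [0, 1), got {ld_rho}")
    if n_samples < 1 or n_markers < 1:
        raise ValueError("n_samples and n_markers must be positive")
    if _smallest_maf(n_samples, homozygous_only) > maf_high:
        raise ValueError(
            f"infeasible MAF band: smallest nonzero MAF at n={n_samples} is "
            f"{_smallest_maf(n_samples, homozygous_only):.4g} > maf_high={maf_high}"
        )

    rng = np.random.default_rng(seed)
    use_blocks = ld_block_size > 0 and ld_rho > 0.0
    if use_blocks:
        n_blocks = -(-n_markers // ld_block_size)
        factors = rng.standard_normal((n_samples, n_blocks))
        block_of = np.arange(n_markers) // ld_block_size
        a, b = np.sqrt(ld_rho), np.sqrt(1.0 - ld_rho)

    values = np.zeros((n_samples, n_markers), dtype=np.int8)

    def draw(cols: np.ndarray) -> np.ndarray:
        q = rng.uniform(maf_low, maf_high, size=cols.size)
        thresh = stats.norm.ppf(q)
        n_draws = 1 if homozygous_only else 2
        g = np.zeros((n_samples, cols.size), dtype=np.int8)
        for _ in range(n_draws):
            eps = rng.standard_normal((n_samples, cols.size))
            z = a * factors[:, block_of[cols]] + b * eps if use_blocks else eps
            g += (z < thresh).astype(np.int8)
        if homozygous_only:
            g *= 2
        return g

    pending = np.arange(n_markers)
    for _round in range(200):
        values[:, pending] = draw(pending)
        maf = compute_maf_values(values)
        bad = (maf <= maf_low) | (maf > maf_high)
        # collision scan: a later column identical to any earlier one is redrawn
        seen: dict[bytes, int] = {}
        for j in range(n_markers):
            key = values[:, j].tobytes()
            if key in seen:
                bad[j] = True
            else:
                seen[key] = j
        pending = np.flatnonzero(bad)
        if pending.size == 0:
            break
    else:
        raise RuntimeError("could not satisfy MAF band / uniqueness after 200 redraw rounds")

    sample_ids = [f"S{i:05d}" for i in range(n_samples)]
    marker_ids = [f"M{j:05d}" for j in range(n_markers)]
    return GenotypeMatrix(sample_ids, marker_ids, values)


def compute_maf_values(values: np.ndarray) -> np.ndarray:
    p = values.sum(axis=0) / (2.0 * values.shape[0])
    return np.minimum(p, 1.0 - p)


def compute_maf(G: GenotypeMatrix) -> np.ndarray:
    """Per-marker minor allele frequency min(p, 1-p), p = allele-count mean / 2."""
    return compute_maf_values(G.values)


def filter_maf(G: GenotypeMatrix, threshold: float) -> GenotypeMatrix:
    """Keep markers with MAF >= ``threshold`` (boundary closed), order preserved."""
    if not (0 <= threshold <= 0.5):
        raise ValueError(f"threshold must be in [0, 0.5], got {threshold}")
    keep = np.flatnonzero(compute_maf(G) >= threshold)
    if keep.size == 0:
        raise ValueError(f"MAF filter at {threshold} removed all {G.n_markers} markers")
    return G.take_markers(keep)


def filter_duplicates(G: GenotypeMatrix) -> GenotypeMatrix:
    """Drop markers identical (after encoding) to an earlier column; first wins."""
    seen: set[bytes] = set()
    keep = []
    for j in range(G.n_markers):
        key = G.values[:, j].tobytes()
        if key not in seen:
            seen.add(key)
            keep.append(j)
    if len(keep) == G.n_markers:
        return G
    return G.take_markers(np.asarray(keep))


def encode(G: GenotypeMatrix, scheme: str) -> EncodedMatrix:
    """Encode allele counts for model consumption.

    ``additive012`` is the identity; ``additive_centered`` maps {0,1,2} to
    {-1,0,1} (the centered coding ridge-type mixed models conventionally use);
    ``onehot`` emits one indicator column per genotype state *observed* at each
    marker, so every row sums to the marker count.
    """
    if scheme == "additive012":
        return EncodedMatrix(scheme, G.values.astype(np.float64), list(G.marker_ids))
    if scheme == "additive_centered":
        return EncodedMatrix(scheme, G.values.astype(np.float64) - 1.0, list(G.marker_ids))
    if scheme == "onehot":
        cols: list[np.ndarray] = []
        groups: list[tuple[int, int]] = []
        for j in range(G.n_markers):
            col = G.values[:, j]
            for state in (0, 1, 2):
                if np.any(col == state):
                    cols.append((col == state).astype(np.float64))
                    groups.append((j, state))
        return EncodedMatrix(scheme, np.column_stack(cols), list(G.marker_ids), groups)
    raise ValueError(f"unknown encoding scheme {scheme!r}; choose from {ENCODING_SCHEMES}")


def decode_onehot(E: EncodedMatrix, sample_ids: list[str] | None = None) -> GenotypeMatrix:
    """Invert a one-hot encoding back to allele counts (round-trip check)."""
    if E.scheme != "onehot" or E.feature_group is None:
        raise ValueError("decode_onehot requires a one-hot EncodedMatrix")
    n = E.values.shape[0]
    m = len(E.marker_ids)
    out = np.zeros((n, m), dtype=np.int8)
    for col, (j, state) in enumerate(E.feature_group):
        out[E.values[:, col] > 0.5, j] = state
    if sample_ids is None:
        sample_ids = [f"S{i:05d}" for i in range(n)]
    return GenotypeMatrix(sample_ids, list(E.marker_ids), out)


def onehot_channels(G: GenotypeMatrix) -> np.ndarray:
    """One-hot view as (n_samples, 3, n_markers) channel tensor for conv nets."""
    n, m = G.values.shape
    out = np.zeros((n, 3, m), dtype=np.float64)
    for state in (0, 1, 2):
        out[:, state, :] = G.values == state
    return out


# ---------------------------------------------------------------------------
# delimited-table I/O


def _detect_sep(first_line: str) -> str:
    return "\t" if first_line.count("\t") >= first_line.count(",") else ","


def write_genotype_table(G: GenotypeMatrix, path, sep: str = ",") -> None:
    df = pd.DataFrame(G.values, index=pd.Index(G.sample_ids, name="sample_id"),
                      columns=G.marker_ids)
    df.to_csv(path, sep=sep)


def read_genotype_table(path) -> GenotypeMatrix:
    """Read a delimited genotype table (header: ``sample_id,<marker>,...``).

    The delimiter (comma or tab) is auto-detected from the header line.
    Malformed cells are reported with their sample/marker location.
    """
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
        if not first.strip():
            raise GenotypeFormatError(f"{path}: empty file / missing header")
        sep = _detect_sep(first)
        # check the raw header before pandas de-duplicates repeated names
        header = [h.strip() for h in first.rstrip("\n").split(sep)]
        if len(header) < 2:
            raise GenotypeFormatError(f"{path}: header must list a sample-id column and markers")
        raw_markers = header[1:]
        dup_m = {m for m in raw_markers if raw_markers.count(m) > 1}
        if dup_m:
            raise GenotypeFormatError(f"{path}: duplicated marker id(s): {sorted(dup_m)}")
        fh.seek(0)
        df = pd.read_csv(fh, sep=sep, dtype=str)
    marker_ids = [str(c) for c in df.columns[1:]]
    sample_ids = [str(s) for s in df.iloc[:, 0]]
    dup_s = {s for s in sample_ids if sample_ids.count(s) > 1}
    if dup_s:
        raise GenotypeFormatError(f"{path}: duplicated sample id(s): {sorted(dup_s)}")
    raw = df.iloc[:, 1:].to_numpy()
    values = np.zeros(raw.shape, dtype=np.int8)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = str(raw[i, j]).strip()
            if cell not in ("0", "1", "2"):
                raise GenotypeFormatError(
                    f"{path}: invalid genotype {cell!r} at sample {sample_ids[i]!r}, "
                    f"marker {marker_ids[j]!r} (row {i + 2}, column {j + 2})"
                )
            values[i, j] = int(cell)
    return GenotypeMatrix(sample_ids, marker_ids, values)


def write_phenotype_table(sample_ids: list[str], y: np.ndarray, path, sep: str = ",") -> None:
    pd.DataFrame({"sample_id": sample_ids, "value": np.asarray(y, dtype=float)}).to_csv(
        path, sep=sep, index=False
    )


def read_phenotype_table(path) -> pd.Series:
    """Read a two-column ``sample_id,value`` table into a float Series."""
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
        if not first.strip():
            raise GenotypeFormatError(f"{path}: empty file / missing header")
        sep = _detect_sep(first)
        fh.seek(0)
        df = pd.read_csv(fh, sep=sep)
    if df.shape[1] != 2:
        raise GenotypeFormatError(f"{path}: expected two columns (sample_id, value)")
    ids = [str(s) for s in df.iloc[:, 0]]
    if len(set(ids)) != len(ids):
        raise GenotypeFormatError(f"{path}: duplicated sample ids")
    try:
        vals = df.iloc[:, 1].astype(float)
    except (TypeError, ValueError) as exc:
        raise GenotypeFormatError(f"{path}: non-numeric phenotype value ({exc})") from exc
    return pd.Series(vals.to_numpy(), index=ids, name="value")
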