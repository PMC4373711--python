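"""Pair counting, potential-table construction and structure scoring.

The score of a type pair (a, b) at distance bin r is the negative log odds
of observing that pair at that distance in the reference library, relative
to the type-independent bin occupancy:

    s_ab(r) = -ln[ (N_obs(a,b,r) / N_obs(r)) / (N_obs(a,b) / N_total) ]

where N_obs(a,b,r) counts library atom pairs of types {a, b} with distance
in bin r, N_obs(a,b) = sum_r N_obs(a,b,r), N_obs(r) = sum_ab N_obs(a,b,r)
and N_total is the grand total.  A structure's score is the sum of s_ab(r)
over all of its eligible atom pairs within the distance cutoff; lower is
more native-like / more stable.

Zero-count cells would make the logarithm diverge, so by default counts are
Laplace-smoothed: each pair class receives a pseudocount alpha spread evenly
over the bins (alpha/n_bins per cell) and all marginals are recomputed from
the smoothed cells.  alpha=0 disables smoothing (used by exact oracles).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .atom_typing import AtomTypeRegistry, default_registry
from .binning import DistanceBinning, bins_of, default_binning
from .errors import IncompatibilityError, InputError, StarpotError
from .structure_io import TypedAtom

FORMAT_LINE = "#format starpot-potential 1"


@dataclass(frozen=True)
class PairingPolicy:
    """Which atom pairs enter counting and scoring.

    min_residue_separation=1 (default) excludes intra-residue pairs only;
    larger values additionally exclude sequence-local pairs within a chain.
    Cross-chain pairs are excluded by default (single-domain scoring).
    """

    min_residue_separation: int = 1
    cross_chain: str = "exclude"  # "include" | "exclude"

    def __post_init__(self) -> None:
        if self.min_residue_separation < 1:
            raise InputError("min_residue_separation must be >= 1")
        if self.cross_chain not in ("include", "exclude"):
            raise InputError(f"bad cross_chain policy: {self.cross_chain!r}")


@dataclass
class PairCountTensor:
    """N_obs(a, b, r) for unordered type pairs, stored in the a <= b triangle."""

    counts: np.ndarray  # (n_types, n_types, n_bins) int64; nonzero only for a <= b
    binning: DistanceBinning
    registry_version: str
    n_structures: int = 0

    @property
    def n_types(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[2]

    def n_obs_ab(self) -> np.ndarray:
        """Per-pair-class marginal N_obs(a,b), shape (n_types, n_types)."""
        return self.counts.sum(axis=2)

    def n_obs_r(self) -> np.ndarray:
        """Per-bin marginal N_obs(r), shape (n_bins,)."""
        return self.counts.sum(axis=(0, 1))

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    def get(self, a: int, b: int, r: int) -> int:
        if a > b:
            a, b = b, a
        return int(self.counts[a, b, r])


@dataclass
class PotentialTable:
    """s_ab(r) per unordered type pair per bin, plus provenance."""

    scores: np.ndarray  # (n_types, n_types, n_bins) float64, symmetric
    binning: DistanceBinning
    smoothing_method: str
    smoothing_alpha: float
    registry_version: str
    n_total: int
    n_structures: int = 0
    counts: Optional[np.ndarray] = None  # raw counts, a <= b triangle

    def score_of(self, a: int, b: int, r: int) -> float:
        return float(self.scores[a, b, r])


@dataclass
class ScoreReport:
    """Result of scoring one structure against a potential table."""

    source_id: str
    n_typed_atoms: int
    n_pairs_counted: int
    raw_score: float

    @property
    def per_pair_score(self) -> Optional[float]:
        if self.n_pairs_counted == 0:
            return None
        return self.raw_score / self.n_pairs_counted


def _pair_arrays(
    atoms: Sequence[TypedAtom],
    binning: DistanceBinning,
    policy: PairingPolicy,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Eligible pairs as (type_a<=type_b arrays, bin indices).

    Enumerates the upper triangle of the distance matrix, applies the
    pairing policy and the distance cutoff.
    """
    n = len(atoms)
    if n == 0:
        raise InputError("no typed atoms to pair")
    coords = np.array([a.coords for a in atoms], dtype=np.float64)
    types = np.array([a.type_index for a in atoms], dtype=np.intp)

    # encode residues: chain ordinal + per-chain residue ordinal (file order)
    chain_ids: dict[str, int] = {}
    res_ids: dict[tuple, int] = {}
    res_ord_in_chain: dict[str, int] = {}
    chain_arr = np.empty(n, dtype=np.intp)
    res_arr = np.empty(n, dtype=np.intp)
    for i, a in enumerate(atoms):
        ch, _ = a.residue_key
        if ch not in chain_ids:
            chain_ids[ch] = len(chain_ids)
            res_ord_in_chain[ch] = 0
        if a.residue_key not in res_ids:
            res_ids[a.residue_key] = res_ord_in_chain[ch]
            res_ord_in_chain[ch] += 1
        chain_arr[i] = chain_ids[ch]
        res_arr[i] = res_ids[a.residue_key]

    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff * diff).sum(axis=2))

    iu, ju = np.triu_indices(n, k=1)
    same_chain = chain_arr[iu] == chain_arr[ju]
    sep_ok = np.abs(res_arr[iu] - res_arr[ju]) >= policy.min_residue_separation
    eligible = np.where(
        same_chain,
        sep_ok,
        policy.cross_chain == "include",
    )
    d = dist[iu, ju]
    eligible &= d < binning.cutoff
    iu, ju, d = iu[eligible], ju[eligible], d[eligible]

    a = types[iu]
    b = types[ju]
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    r = bins_of(d, binning)
    return lo, hi, r


def count_pairs(
    atoms: Sequence[TypedAtom],
    binning: Optional[DistanceBinning] = None,
    policy: Optional[PairingPolicy] = None,
    registry: Optional[AtomTypeRegistry] = None,
) -> PairCountTensor:
    """Accumulate N_obs(a,b,r) over all policy-eligible pairs of one structure."""
    if binning is None:
        binning = default_binning()
    if policy is None:
        policy = PairingPolicy()
    if registry is None:
        registry = default_registry()
    lo, hi, r = _pair_arrays(atoms, binning, policy)
    counts = np.zeros((registry.size, registry.size, binning.n_bins), dtype=np.int64)
    np.add.at(counts, (lo, hi, r), 1)
    return PairCountTensor(
        counts=counts,
        binning=binning,
        registry_version=registry.version,
        n_structures=1,
    )


def merge_counts(tensors: Sequence[PairCountTensor]) -> PairCountTensor:
    """Cellwise sum of count tensors sharing binning and registry."""
    if not tensors:
        raise InputError("nothing to merge")
    first = tensors[0]
    total = np.zeros_like(first.counts)
    n_structures = 0
    for t in tensors:
        if t.binning != first.binning:
            raise IncompatibilityError("cannot merge counts with different binnings")
        if t.registry_version != first.registry_version:
            raise IncompatibilityError("cannot merge counts from different registries")
        if t.counts.shape != first.counts.shape:
            raise IncompatibilityError("cannot merge counts of different shapes")
        total += t.counts
        n_structures += t.n_structures
    return PairCountTensor(
        counts=total,
        binning=first.binning,
        registry_version=first.registry_version,
        n_structures=n_structures,
    )


def build_potential(
    counts: PairCountTensor,
    smoothing: str = "laplace",
    alpha: float = 1.0,
) -> PotentialTable:
    """Turn observed pair counts into a log-odds score table.

    smoothing="laplace" adds alpha/n_bins to every cell of every pair class
    before taking ratios (marginals recomputed from smoothed cells), which
    keeps every score finite.  smoothing="none" or alpha=0 uses raw counts;
    then cells with zero count in a populated pair class score +inf, and
    pair classes never observed score 0 by convention.
    """
    if counts.n_total == 0:
        raise InputError("empty library: no pair counts")
    if smoothing not in ("laplace", "none"):
        raise InputError(f"unknown smoothing method: {smoothing!r}")
    if smoothing == "none":
        alpha = 0.0
    if alpha < 0:
        raise InputError("smoothing alpha must be >= 0")

    n_types, _, n_bins = counts.counts.shape
    tri = np.triu_indices(n_types)  # a <= b pair classes
    raw = counts.counts[tri].astype(np.float64)  # (n_pairs, n_bins)

    smoothed = raw + alpha / n_bins
    n_ab = smoothed.sum(axis=1)  # (n_pairs,)
    n_r = smoothed.sum(axis=0)  # (n_bins,)
    n_total = smoothed.sum()

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (smoothed / n_r[None, :]) / (n_ab[:, None] / n_total)
        s = -np.log(ratio)
    # 0/0 cases (possible only when alpha=0): a pair class never observed,
    # or a bin empty across the whole library.  Such cells carry no
    # information -> score 0.  A zero cell inside a populated pair class and
    # bin stays +inf (the raw log-odds genuinely diverges there).
    s[n_ab == 0, :] = 0.0
    s[np.isnan(s)] = 0.0

    scores = np.zeros((n_types, n_types, n_bins), dtype=np.float64)
    scores[tri] = s
    scores[tri[1], tri[0]] = s  # symmetrize for direct (a, b) lookup

    return PotentialTable(
        scores=scores,
        binning=counts.binning,
        smoothing_method=smoothing if alpha > 0 else "none",
        smoothing_alpha=float(alpha),
        registry_version=counts.registry_version,
        n_total=counts.n_total,
        n_structures=counts.n_structures,
        counts=counts.counts.copy(),
    )


def score_structure(
    atoms: Sequence[TypedAtom],
    table: PotentialTable,
    policy: Optional[PairingPolicy] = None,
    source_id: str = "",
    registry: Optional[AtomTypeRegistry] = None,
) -> ScoreReport:
    """Sum s_ab(r) over all policy-eligible pairs of a structure."""
    if policy is None:
        policy = PairingPolicy()
    if registry is None:
        registry = default_registry()
    if table.registry_version != registry.version:
        raise IncompatibilityError(
            f"potential built for registry {table.registry_version!r}, "
            f"atoms typed with {registry.version!r}"
        )
    if len(atoms) == 0:
        return ScoreReport(source_id=source_id, n_typed_atoms=0, n_pairs_counted=0, raw_score=0.0)
    lo, hi, r = _pair_arrays(atoms, table.binning, policy)
    raw = float(table.scores[lo, hi, r].sum()) if lo.size else 0.0
    return ScoreReport(
        source_id=source_id,
        n_typed_atoms=len(atoms),
        n_pairs_counted=int(lo.size),
        raw_score=raw,
    )


# ---------------------------------------------------------------------------
# potential file format (bit-exact TSV)

def write_potential(
    table: PotentialTable,
    path,
    registry: Optional[AtomTypeRegistry] = None,
) -> None:
    """Write a potential table as the versioned TSV format.

    Header lines carry format version, registry version, bin edges,
    smoothing and N_total; the body has one row per (a <= b, bin) cell with
    the raw count and the score at 9 significant digits, sorted by
    (type_a, type_b, bin).  Output is byte-reproducible.
    """
    if registry is None:
        registry = default_registry()
    if table.counts is None:
        raise InputError("table has no counts; cannot serialize")
    n_types, _, n_bins = table.scores.shape
    buf = io.StringIO()
    buf.write(FORMAT_LINE + "\n")
    buf.write(f"#registry {table.registry_version}\n")
    buf.write(f"#edges {table.binning.serialize_edges()}\n")
    buf.write(f"#smoothing {table.smoothing_method} {table.smoothing_alpha:g}\n")
    buf.write(f"#n_total {table.n_total}\n")
    buf.write(f"#n_structures {table.n_structures}\n")
    labels = [registry.label(i) for i in range(n_types)]
    ai, bi = np.triu_indices(n_types)
    cnt = table.counts
    sc = table.scores
    for a, b in zip(ai, bi):
        la, lb = labels[a], labels[b]
        for r in range(n_bins):
            buf.write(f"{la}\t{lb}\t{r}\t{int(cnt[a, b, r])}\t{sc[a, b, r]:.9g}\n")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(buf.getvalue())


def read_potential(path, registry: Optional[AtomTypeRegistry] = None) -> PotentialTable:
    """Read a potential table written by :func:`write_potential`."""
    if registry is None:
        registry = default_registry()
    header: dict[str, str] = {}
    rows_a: list[int] = []
    rows_b: list[int] = []
    rows_r: list[int] = []
    rows_c: list[int] = []
    rows_s: list[float] = []
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline().rstrip("\n")
        if first != FORMAT_LINE:
            raise InputError(f"not a starpot potential file: {path}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition(" ")
                header[key] = val
                continue
            la, lb, r, c, s = line.split("\t")
            rows_a.append(registry.index_of_label(la))
            rows_b.append(registry.index_of_label(lb))
            rows_r.append(int(r))
            rows_c.append(int(c))
            rows_s.append(float(s))
    try:
        binning = DistanceBinning.from_serialized(header["edges"])
        method, alpha_s = header["smoothing"].split()
        n_total = int(header["n_total"])
        reg_version = header["registry"]
    except (KeyError, ValueError) as exc:
        raise InputError(f"malformed potential header in {path}: {exc}") from exc
    if reg_version != registry.version:
        raise IncompatibilityError(
            f"potential file registry {reg_version!r} != loaded registry {registry.version!r}"
        )
    n_types = registry.size
    scores = np.zeros((n_types, n_types, binning.n_bins), dtype=np.float64)
    cnts = np.zeros((n_types, n_types, binning.n_bins), dtype=np.int64)
    a = np.asarray(rows_a)
    b = np.asarray(rows_b)
    r = np.asarray(rows_r)
    scores[a, b, r] = rows_s
    scores[b, a, r] = rows_s
    cnts[a, b, r] = rows_c
    return PotentialTable(
        scores=scores,
        binning=binning,
        smoothing_method=method,
        smoothing_alpha=float(alpha_s),
        registry_version=reg_version,
        n_total=n_total,
        n_structures=int(header.get("n_structures", 0)),
        counts=cnts,
    )
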