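"""Triplet synergy scan: triangle filter, permutation test, FDR control.

The pipeline mirrors how synergistic sign associations are hunted in
cross-sectional survey data:

1. keep only variable triples whose three pairwise MIs are all below a
   threshold (default 0.05 bits) -- exactly the triples a pairwise analysis
   would dismiss;
2. score each candidate with the plug-in O-information and compare it to a
   null in which each of the three columns is independently row-shuffled
   (destroying all dependence while preserving marginals);
3. adjust the one-sided (synergy-direction) permutation p-values with
   Benjamini-Hochberg and flag candidates at the chosen FDR level.

The permutation engine bit-packs the shuffled columns and obtains all eight
contingency cells of a triple from three AND-popcount reductions, which
makes thousands of candidates x thousands of permutations tractable.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .info import DataMatrix, mi_matrix, o_information

__all__ = [
    "ScanConfig",
    "TripletResult",
    "PermutationTestResult",
    "ConditionalProfile",
    "triangle_filter",
    "permutation_pvalue",
    "bh_adjust",
    "scan",
    "conditional_profile",
]


@dataclass(frozen=True)
class ScanConfig:
    """Scan settings: MI filter threshold (bits), permutation count, FDR level."""

    mi_threshold: float = 0.05
    permutations: int = 1000
    fdr_q: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mi_threshold < 0:
            raise ValueError("mi_threshold must be >= 0")
        if self.permutations < 99:
            raise ValueError("permutations must be >= 99")
        if not (0.0 < self.fdr_q < 1.0):
            raise ValueError("fdr_q must be in (0, 1)")


@dataclass(frozen=True)
class TripletResult:
    """One candidate triple: pairwise MIs, O-information, p, q, verdict."""

    labels: tuple[str, str, str]
    mi_ab: float
    mi_ac: float
    mi_bc: float
    omega: float
    p_value: float
    q_value: float
    significant: bool


@dataclass(frozen=True)
class PermutationTestResult:
    labels: tuple[str, str, str]
    omega: float
    p_value: float  # one-sided toward negative (synergistic) O-information
    p_value_two_sided: float
    null_mean: float
    null_sd: float
    permutations: int
    degenerate: bool


def _entropy_from_counts(counts: np.ndarray, n: int) -> np.ndarray:
    """Shannon entropy (bits) along the last axis of a count array."""
    p = counts / float(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return -terms.sum(axis=-1)


def _pair_entropy(ka: int, kb: int, nab: np.ndarray, n: int) -> np.ndarray:
    cells = np.stack([n - ka - kb + nab, kb - nab, ka - nab, nab], axis=-1)
    return _entropy_from_counts(cells, n)


def _popcount(packed: np.ndarray) -> np.ndarray:
    return np.bitwise_count(packed).sum(axis=-1, dtype=np.int64)


class _PackedColumns:
    """Bit-packed observed and row-shuffled columns for the permutation null.

    Each column gets its own RNG stream (spawned from the scan seed in a
    fixed label order), and all candidate triples share the same B shuffles
    per column -- valid because the null only requires the three columns to
    be mutually independent.
    """

    def __init__(self, frame: pd.DataFrame, labels, permutations: int, seed: int):
        self.n = int(frame.shape[0])
        self.b = int(permutations)
        labels = list(labels)
        children = np.random.SeedSequence(seed).spawn(len(labels))
        self.obs: dict[str, np.ndarray] = {}
        self.perm: dict[str, np.ndarray] = {}
        self.ones: dict[str, int] = {}
        for label, child in zip(labels, children):
            col = frame[label].to_numpy(dtype=np.uint8)
            self.obs[label] = np.packbits(col)[None, :]
            self.ones[label] = int(col.sum())
            rng = np.random.default_rng(child)
            tiled = np.tile(col, (self.b, 1))
            rng.permuted(tiled, axis=1, out=tiled)
            self.perm[label] = np.packbits(tiled, axis=1)

    def omega(self, a: str, b: str, c: str, null: bool) -> np.ndarray:
        """Plug-in O-information of (a, b, c); observed (length 1) or null (length B)."""
        src = self.perm if null else self.obs
        pa, pb, pc = src[a], src[b], src[c]
        ka, kb, kc = self.ones[a], self.ones[b], self.ones[c]
        n = self.n
        nab = _popcount(pa & pb)
        nac = _popcount(pa & pc)
        nbc = _popcount(pb & pc)
        nabc = _popcount(pa & pb & pc)
        cells = np.stack(
            [
                n - ka - kb - kc + nab + nac + nbc - nabc,
                kc - nac - nbc + nabc,
                kb - nab - nbc + nabc,
                nbc - nabc,
                ka - nab - nac + nabc,
                nac - nabc,
                nab - nabc,
                nabc,
            ],
            axis=-1,
        )
        h3 = _entropy_from_counts(cells, n)
        h1 = (
            _entropy_from_counts(np.array([n - ka, ka]), n)
            + _entropy_from_counts(np.array([n - kb, kb]), n)
            + _entropy_from_counts(np.array([n - kc, kc]), n)
        )
        hab = _pair_entropy(ka, kb, nab, n)
        hac = _pair_entropy(ka, kc, nac, n)
        hbc = _pair_entropy(kb, kc, nbc, n)
        return h3 + h1 - hab - hac - hbc


def triangle_filter(data: DataMatrix, cfg: ScanConfig) -> list[tuple[str, str, str]]:
    """All unordered triples whose three pairwise MIs are each below threshold.

    These are precisely the triples invisible to a pairwise association
    network.  Output is deterministic: triples in lexicographic label order.
    """
    if data.m < 3:
        raise ValueError("triangle_filter needs at least 3 columns")
    matrix = mi_matrix(data)
    labels = sorted(data.columns)
    out = []
    for a, b, c in itertools.combinations(labels, 3):
        if (
            matrix.loc[a, b] < cfg.mi_threshold
            and matrix.loc[a, c] < cfg.mi_threshold
            and matrix.loc[b, c] < cfg.mi_threshold
        ):
            out.append((a, b, c))
    return out


def _pvalues_from_null(omega_obs: float, null: np.ndarray) -> tuple[float, float]:
    b = null.size
    tol = 1e-12
    one_sided = (1 + int((null <= omega_obs + tol).sum())) / (b + 1)
    upper = (1 + int((null >= omega_obs - tol).sum())) / (b + 1)
    two_sided = min(1.0, 2.0 * min(one_sided, upper))
    return one_sided, two_sided


def permutation_pvalue(
    data: DataMatrix, triplet, cfg: ScanConfig
) -> PermutationTestResult:
    """One-sided permutation p-value for a triple's O-information.

    Small p means the observed O-information lies far into the synergistic
    (negative) tail of the independently-shuffled null.  The +1 smoothing
    keeps the test valid at finite B (p >= 1/(B+1)).  RNG streams are
    assigned to the triple's columns in sorted label order, so the result is
    reproducible and independent of how the triple is written.
    """
    labels = tuple(triplet)
    if len(labels) != 3 or len(set(labels)) != 3:
        raise ValueError(f"triplet must hold three distinct labels, got {labels}")
    missing = [x for x in labels if x not in data.columns]
    if missing:
        raise ValueError(f"unknown column label(s): {missing}")
    constant = [x for x in labels if data.frame[x].nunique() < 2]
    if constant:
        warnings.warn(
            f"degenerate triplet {labels}: constant column(s) {constant}; p = 1",
            stacklevel=2,
        )
        return PermutationTestResult(
            labels=labels,
            omega=0.0,
            p_value=1.0,
            p_value_two_sided=1.0,
            null_mean=0.0,
            null_sd=0.0,
            permutations=cfg.permutations,
            degenerate=True,
        )
    packed = _PackedColumns(data.frame, sorted(labels), cfg.permutations, cfg.seed)
    omega_obs = float(packed.omega(*labels, null=False)[0])
    null = packed.omega(*labels, null=True)
    p1, p2 = _pvalues_from_null(omega_obs, null)
    return PermutationTestResult(
        labels=labels,
        omega=omega_obs,
        p_value=p1,
        p_value_two_sided=p2,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)),
        permutations=cfg.permutations,
        degenerate=False,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (q-values), input order kept."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def scan(data: DataMatrix, cfg: ScanConfig) -> list[TripletResult]:
    """Full pipeline: triangle filter -> O-information + permutation p -> BH.

    BH is applied over exactly the filtered candidate set (post-selection,
    as in the field's practice; approximate because filtering and testing
    use the same data).  Results are sorted by q-value then O-information
    ascending, so the most credibly synergistic triples come first.
    """
    if data.m < 3:
        raise ValueError("scan needs at least 3 columns")
    matrix = mi_matrix(data)
    candidates = triangle_filter(data, cfg)
    if not candidates:
        return []
    involved = sorted({x for tri in candidates for x in tri})
    packed = _PackedColumns(data.frame, involved, cfg.permutations, cfg.seed)
    omegas: list[float] = []
    pvals: list[float] = []
    for a, b, c in candidates:
        omega_obs = float(packed.omega(a, b, c, null=False)[0])
        null = packed.omega(a, b, c, null=True)
        p1, _ = _pvalues_from_null(omega_obs, null)
        omegas.append(omega_obs)
        pvals.append(p1)
    qvals = bh_adjust(pvals)
    results = [
        TripletResult(
            labels=(a, b, c),
            mi_ab=float(matrix.loc[a, b]),
            mi_ac=float(matrix.loc[a, c]),
            mi_bc=float(matrix.loc[b, c]),
            omega=omega,
            p_value=p,
            q_value=float(q),
            significant=bool(q <= cfg.fdr_q),
        )
        for (a, b, c), omega, p, q in zip(candidates, omegas, pvals, qvals)
    ]
    results.sort(key=lambda r: (r.q_value, r.omega, r.labels))
    return results


@dataclass(frozen=True)
class ConditionalProfile:
    """P(target=1) under each configuration of one or two conditioning signs."""

    target: str
    given: tuple[str, ...]
    marginal: float
    table: pd.DataFrame  # columns: *given, n, p_target (NaN where undefined)

    def __str__(self) -> str:  # pragma: no cover - convenience display
        lines = [f"P({self.target}=1) = {self.marginal:.3f}"]
        for _, row in self.table.iterrows():
            cond = ", ".join(f"{g}={int(row[g])}" for g in self.given)
            p = row["p_target"]
            txt = "undefined (empty cell)" if pd.isna(p) else f"{p:.3f}"
            lines.append(f"P({self.target}=1 | {cond}) = {txt}  [n={int(row['n'])}]")
        return "\n".join(lines)


def conditional_profile(data: DataMatrix, target: str, given) -> ConditionalProfile:
    """Conditional prevalence of ``target`` given one or two other signs.

    The signature of a synergistic triple: conditioning on either sign alone
    barely moves the target's prevalence, while conditioning on both moves
    it strongly.  Empty conditioning cells yield NaN, never a silent 0.
    """
    given = list(given)
    if len(given) not in (1, 2):
        raise ValueError("given must hold one or two labels")
    labels = [target] + given
    if len(set(labels)) != len(labels):
        raise ValueError(f"labels must be distinct, got {labels}")
    missing = [x for x in labels if x not in data.columns]
    if missing:
        raise ValueError(f"unknown column label(s): {missing}")
    frame = data.frame
    rows = []
    for combo in itertools.product((0, 1), repeat=len(given)):
        mask = np.ones(len(frame), dtype=bool)
        for g, v in zip(given, combo):
            mask &= frame[g].to_numpy() == v
        count = int(mask.sum())
        p = float(frame.loc[mask, target].mean()) if count else float("nan")
        rows.append(dict(zip(given, combo)) | {"n": count, "p_target": p})
    return ConditionalProfile(
        target=target,
        given=tuple(given),
        marginal=float(frame[target].mean()),
        table=pd.DataFrame(rows),
    )
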