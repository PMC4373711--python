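"""Decoy discrimination metrics and score-vs-stability correlation.

Ships the published benchmark for consensus tetratricopeptide-repeat (TPR)
proteins: nine designed proteins (CTPRa2..CTPRa10 and CTPR2/CTPR3) with
their equilibrium unfolding free energies ΔG_D-N (Gibbs-Helmholtz analysis
of thermal denaturation), the Ising-model folding free energies ΔG_0->j
where measured, and their repeat-specific RAPDF scores.  Squared Pearson
correlation of score against either energy quantifies how well the
potential tracks measured stability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, InputError
from .potential import ScoreReport

FIXTURE_NAME = "ctpr_stability.tsv"


@dataclass(frozen=True)
class StabilityRecord:
    """One protein's measured stability and its statistical score."""

    label: str
    dg_dn: Optional[float]  # kcal/mol, unfolding free energy
    dg_dn_err: Optional[float]
    dg_0j: Optional[float]  # kcal/mol, Ising-model folding free energy
    dg_0j_err: Optional[float]
    rapdf_score: float  # dimensionless, lower = more stable


@dataclass
class DiscriminationResult:
    """Native-vs-decoy outcome under the lower-is-more-stable convention."""

    native_score: float
    decoy_scores: list[float]
    delta: float  # native - min(decoy); negative when the native wins clearly
    rank_of_native: int  # 1-based among native + decoys sorted ascending


def _fixture_frame() -> pd.DataFrame:
    with resources.files("starpot").joinpath("data", FIXTURE_NAME).open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def ctpr_stability_fixture() -> list[StabilityRecord]:
    """The nine-protein consensus-TPR stability panel, values as published."""
    records = []
    for row in _fixture_frame().itertuples(index=False):
        records.append(
            StabilityRecord(
                label=row.label,
                dg_dn=None if pd.isna(row.dg_dn) else float(row.dg_dn),
                dg_dn_err=None if pd.isna(row.dg_dn_err) else float(row.dg_dn_err),
                dg_0j=None if pd.isna(row.dg_0j) else float(row.dg_0j),
                dg_0j_err=None if pd.isna(row.dg_0j_err) else float(row.dg_0j_err),
                rapdf_score=float(row.rapdf_tpr),
            )
        )
    return records


def squared_pearson(xs: Sequence[float], ys: Sequence[float]) -> float:
    """R²: squared Pearson product-moment correlation of paired values."""
    if len(xs) != len(ys):
        raise InputError(f"length mismatch: {len(xs)} vs {len(ys)}")
    if len(xs) < 3:
        raise InputError("need at least 3 paired values")
    if len(set(xs)) == 1 or len(set(ys)) == 1:
        raise DegenerateInputError("constant input sequence")
    r = stats.pearsonr(xs, ys).statistic
    return float(r * r)


def fixture_correlations() -> dict[str, float]:
    """R² of score vs each energy on the packaged TPR panel.

    ``score_vs_dg_dn`` uses all nine proteins; ``score_vs_dg_0j`` the seven
    CTPRan proteins for which the Ising-model energy was measured.
    """
    recs = ctpr_stability_fixture()
    dn = [(r.rapdf_score, r.dg_dn) for r in recs if r.dg_dn is not None]
    oj = [(r.rapdf_score, r.dg_0j) for r in recs if r.dg_0j is not None]
    return {
        "score_vs_dg_dn": squared_pearson(*zip(*dn)),
        "score_vs_dg_0j": squared_pearson(*zip(*oj)),
        "n_dg_dn": len(dn),
        "n_dg_0j": len(oj),
    }


def evaluate_decoys(
    native: ScoreReport,
    decoys: Sequence[ScoreReport],
) -> DiscriminationResult:
    """Rank the native among its decoys (lower score = more stable).

    Ties between the native and a decoy favor the native, so a decoy that
    is an exact copy does not demote the native.
    """
    if not decoys:
        raise InputError("need at least one decoy")
    decoy_scores = [d.raw_score for d in decoys]
    ns = native.raw_score
    rank = 1 + sum(1 for s in decoy_scores if s < ns and not math.isclose(s, ns))
    return DiscriminationResult(
        native_score=ns,
        decoy_scores=decoy_scores,
        delta=ns - min(decoy_scores),
        rank_of_native=rank,
    )
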