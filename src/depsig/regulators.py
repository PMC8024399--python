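"""Open upstream-regulator scoring against user-supplied target sets.

Given a differential-expression gene list and a collection of
transcription-factor target sets (e.g. ChIP-seq-derived lists in GMT
form), each regulator gets:

* an overlap p-value — the hypergeometric upper tail of the observed
  overlap between its targets and the DE list within the expressed-gene
  universe (equivalently a one-sided Fisher exact test on the 2×2
  target/non-target × DE/non-DE table);
* a signed activation z-score,
  ``z = (n_consistent − n_inconsistent) / sqrt(N)`` over the N
  overlapping targets with a known expected direction, where consistent
  means the observed DE direction matches the direction expected under
  regulator activation.

Regulators significant at the conventional overlap cutoff p < 0.001 are
reported alongside BH-adjusted q-values, and a comparison table lines up
activation z-scores across contrasts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import DEResult
from .io import GeneSetCollection
from .diffexpr import bh_adjust

logger = logging.getLogger(__name__)

__all__ = ["RegulatorScore", "overlap_test", "activation_zscore", "score_regulators", "compare_contrasts"]

OVERLAP_P_CUTOFF = 0.001


@dataclass
class RegulatorScore:
    regulator: str
    n_targets_in_universe: int
    n_overlap: int
    overlap_p: float
    activation_z: float
    contrast: str
    n_directional: int = 0


def overlap_test(de_genes, targets, universe) -> tuple[int, float]:
    """Hypergeometric upper-tail overlap of a target set with a DE list.

    ``P(X >= n_overlap)`` for X ~ Hypergeometric(N=|universe|,
    K=|targets ∩ universe|, n=|de_genes|).  Target genes outside the
    universe are discarded first; DE genes must be a subset of the
    universe.
    """
    universe = set(universe)
    de = set(de_genes)
    if not universe:
        raise ValueError("empty universe")
    if not de:
        raise ValueError("empty DE list")
    stray = de - universe
    if stray:
        raise ValueError(f"DE genes outside the universe: {sorted(stray)[:5]}")
    k_set = set(targets) & universe
    n_overlap = len(de & k_set)
    if not k_set:
        return 0, 1.0
    p = float(stats.hypergeom.sf(n_overlap - 1, len(universe), len(k_set), len(de)))
    return n_overlap, min(p, 1.0)


def activation_zscore(de_table: pd.DataFrame, directions: dict[str, int]) -> tuple[float, int]:
    """Signed consistency z-score over overlapping directional targets.

    ``directions`` maps target gene → expected direction under regulator
    activation (+1 up, −1 down).  Observed direction comes from the DE
    table's ``direction`` column.  Returns (z, N); N = 0 yields z = 0.
    """
    obs = de_table["direction"]
    overlap = [g for g in directions if g in de_table.index]
    if not overlap:
        return 0.0, 0
    signs = np.array(
        [1 if (obs[g] == "up") == (directions[g] == 1) else -1 for g in overlap]
    )
    return float(signs.sum() / np.sqrt(len(signs))), len(signs)


def score_regulators(
    de_result: DEResult,
    sets: GeneSetCollection,
    universe,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Score every regulator against one contrast's significant genes.

    Returns a table indexed by regulator with overlap counts,
    hypergeometric p, BH q across regulators, activation z and the
    ``significant`` flag at the conventional raw cutoff p < 0.001.
    """
    universe = [g for g in universe]
    de_genes = [g for g in de_result.significant(fdr).index if g in set(universe)]
    if not de_genes:
        raise ValueError(f"no significant genes in contrast {de_result.contrast!r}")
    sig = de_result.significant(fdr)
    rows = []
    for name in sets.names():
        targets = sets[name]
        k_in_universe = len(set(targets) & set(universe))
        if k_in_universe == 0:
            logger.warning("regulator %s has no targets in the universe", name)
            rows.append((name, 0, 0, 1.0, 0.0, 0))
            continue
        n_overlap, p = overlap_test(de_genes, targets, universe)
        dirs = sets.directions.get(name, {})
        dirs_sig = {g: d for g, d in dirs.items() if g in sig.index}
        z, n_dir = activation_zscore(sig, dirs_sig)
        rows.append((name, k_in_universe, n_overlap, p, z, n_dir))
    out = pd.DataFrame(
        rows,
        columns=["regulator", "n_targets_in_universe", "n_overlap", "overlap_p", "activation_z", "n_directional"],
    ).set_index("regulator")
    out["overlap_q"] = bh_adjust(out["overlap_p"].to_numpy())
    out["significant"] = out["overlap_p"] < OVERLAP_P_CUTOFF
    out["contrast"] = de_result.contrast
    return out.sort_values("overlap_p", kind="stable")


def compare_contrasts(scores: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Regulators × contrasts matrix of activation z, sorted by max |z|.

    ``scores`` maps contrast name → the table from
    :func:`score_regulators`.  Overlap p-values ride along as
    ``p:<contrast>`` columns.  Contrasts scored against different
    universes are combined with a warning (union of regulators).
    """
    if len(scores) < 2:
        raise ValueError("need at least 2 contrasts to compare")
    if any(t.empty for t in scores.values()):
        raise ValueError("empty regulator score table")
    universes = {c: set(t.index) for c, t in scores.items()}
    if len(set(map(frozenset, universes.values()))) > 1:
        logger.warning("contrasts scored different regulator sets; using the union")
    z = pd.DataFrame({c: t["activation_z"] for c, t in scores.items()})
    p = pd.DataFrame({f"p:{c}": t["overlap_p"] for c, t in scores.items()})
    wide = pd.concat([z, p], axis=1)
    order = z.abs().max(axis=1).sort_values(ascending=False).index
    return wide.loc[order]
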