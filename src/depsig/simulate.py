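"""Synthetic paired pre/post-surgery cohort generator.

The generator emulates the statistical structure the analysis assumes in
a bariatric-surgery depression cohort: obese patients sampled before and
after surgery, a subset diagnosed with MDD, clinician-rated MADRS scores
per group and timepoint, and whole-blood expression in which a small
number of transcription-factor programs track depression severity.

Generative model (all on the log2 expression scale):

* MADRS for each (group, timepoint) cell is drawn from a normal with the
  cohort's published group means/SDs, truncated at zero (MADRS cannot be
  negative).
* Each regulator ``r`` has a latent activation per sample,
  ``a_r(i) = alpha_r * zMADRS(i) + eps``, with ``eps ~ N(0, 1)`` and
  zMADRS the MADRS score standardized across all simulated samples.
  Because post-surgery MADRS is drawn from the (remitted) post
  distribution, remission propagates to the latent — and hence to the
  biomarker — by construction.
* A target gene ``g`` of regulator ``r`` reads
  ``x(g, i) = baseline_g + u(g, patient) + b_g * a_r(i) + N(0, noise_sd)``
  with ``b_g`` drawn positive; ``u`` is a patient-level offset that makes
  the paired design informative.  Non-target genes drop the ``b_g a_r``
  term.
* A fraction of patients is lost to follow-up (no post sample), split
  across groups proportionally to group size.

With ``coupling_alpha = 0`` target and non-target genes are statistically
exchangeable — the null configuration used for calibration tests.

``simulate_reference`` builds a companion cell-type reference matrix on
the same gene universe: each cell type owns a disjoint block of marker
genes elevated by a fixed log2 offset over a common baseline.  When
``mixture_on`` is set, regulator targets are drawn from the marker blocks
of lymphoid cell types (CD4 T, CD8 T, NK), so that differential genes
carry a cell-of-origin signal for transcript origin analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import CohortDesign, ExpressionMatrix, GeneSetCollection

__all__ = ["SimulationConfig", "simulate_cohort", "simulate_reference", "CELL_TYPES"]

CELL_TYPES = ("monocytes", "dendritic", "CD4_T", "CD8_T", "B", "NK")

#: group × timepoint MADRS mean/SD (points) for the emulated cohort
DEFAULT_MADRS_PARAMS: dict[tuple[str, str], tuple[float, float]] = {
    ("MDD", "baseline"): (19.00, 3.87),
    ("nonMDD", "baseline"): (6.56, 3.59),
    ("MDD", "post"): (6.36, 5.09),
    ("nonMDD", "post"): (2.08, 3.29),
}

DEFAULT_REGULATORS = ("TP53", "NR3C1", "RELA")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the emulated study: 33 patients (15 MDD / 18 non-MDD),
    9 lost to follow-up (4 MDD / 5 non-MDD), MADRS distributions per
    group and timepoint as published.  ``coupling_alpha`` is the latent
    activation shift (z-units) per SD of MADRS; ``noise_sd`` the residual
    expression SD in log2 units.
    """

    n_patients: int = 33
    frac_mdd: float = 15 / 33
    n_genes: int = 1000
    n_regulators: int = 3
    targets_per_regulator: int = 40
    coupling_alpha: float | Sequence[float] = 1.5
    noise_sd: float = 0.5
    madrs_params: Mapping[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MADRS_PARAMS)
    )
    dropout_frac: float = 9 / 33
    n_cell_types: int = 6
    markers_per_type: int = 50
    marker_offset: float = 3.0
    mixture_on: bool = False
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    patient_sd: float = 0.3
    seed: int = 0

    def alphas(self) -> np.ndarray:
        a = np.asarray(self.coupling_alpha, dtype=float)
        if a.ndim == 0:
            a = np.repeat(float(a), self.n_regulators)
        if a.shape != (self.n_regulators,):
            raise ValueError("coupling_alpha must be scalar or length n_regulators")
        return a

    def validate(self) -> None:
        if not (0.0 <= self.frac_mdd <= 1.0):
            raise ValueError("frac_mdd must lie in [0, 1]")
        if not (0.0 <= self.dropout_frac <= 1.0):
            raise ValueError("dropout_frac must lie in [0, 1]")
        if self.n_regulators * self.targets_per_regulator > self.n_genes:
            raise ValueError("n_regulators × targets_per_regulator exceeds n_genes")
        for key, (_, sd) in self.madrs_params.items():
            if sd <= 0:
                raise ValueError(f"MADRS SD for {key} must be > 0")
        if self.noise_sd <= 0 or self.baseline_sd <= 0:
            raise ValueError("noise_sd and baseline_sd must be > 0")
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")
        self.alphas()

    def regulator_names(self) -> list[str]:
        names = list(DEFAULT_REGULATORS[: self.n_regulators])
        while len(names) < self.n_regulators:
            names.append(f"TF{len(names) + 1}")
        return names

    def cell_type_names(self) -> list[str]:
        names = list(CELL_TYPES[: self.n_cell_types])
        while len(names) < self.n_cell_types:
            names.append(f"cell{len(names) + 1}")
        return names


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i + 1:0{width}d}" for i in range(n)]


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def _marker_blocks(config: SimulationConfig) -> dict[str, list[str]]:
    if config.n_cell_types < 2:
        raise ValueError("need at least 2 cell types")
    if config.markers_per_type < 1:
        raise ValueError("markers_per_type must be >= 1")
    needed = config.n_cell_types * config.markers_per_type
    if needed > config.n_genes:
        raise ValueError(
            f"marker blocks need {needed} genes but n_genes = {config.n_genes}"
        )
    genes = _gene_ids(config.n_genes)
    blocks: dict[str, list[str]] = {}
    for c, name in enumerate(config.cell_type_names()):
        lo = c * config.markers_per_type
        blocks[name] = genes[lo : lo + config.markers_per_type]
    return blocks


def _assign_targets(config: SimulationConfig, rng: np.random.Generator) -> dict[str, list[str]]:
    """Disjoint target blocks per regulator.

    Without mixture structure, targets are drawn from the tail of the
    gene list (outside any marker block) so that cell-type and regulator
    signals stay orthogonal.  With ``mixture_on``, regulator targets come
    from lymphoid marker blocks (CD4 T, CD8 T, NK cycling per regulator).
    """
    genes = _gene_ids(config.n_genes)
    names = config.regulator_names()
    if config.mixture_on:
        blocks = _marker_blocks(config)
        lymphoid = [n for n in ("CD4_T", "CD8_T", "NK") if n in blocks]
        if not lymphoid:
            lymphoid = list(blocks)
        if config.targets_per_regulator > config.markers_per_type:
            raise ValueError("mixture_on requires targets_per_regulator <= markers_per_type")
        targets = {}
        for r, name in enumerate(names):
            block = blocks[lymphoid[r % len(lymphoid)]]
            targets[name] = list(block[: config.targets_per_regulator])
        return targets
    n_marker = config.n_cell_types * config.markers_per_type
    pool = genes[n_marker:] if n_marker + config.n_regulators * config.targets_per_regulator <= config.n_genes else genes
    chosen = rng.choice(len(pool), size=config.n_regulators * config.targets_per_regulator, replace=False)
    chosen.sort()
    targets = {}
    for r, name in enumerate(names):
        idx = chosen[r * config.targets_per_regulator : (r + 1) * config.targets_per_regulator]
        targets[name] = [pool[i] for i in idx]
    return targets


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, CohortDesign, GeneSetCollection, dict]:
    """Generate an expression matrix, design, target sets and truth record.

    Returns
    -------
    (ExpressionMatrix, CohortDesign, GeneSetCollection, dict)
        The truth record carries the latent activations (samples ×
        regulators), per-gene effect sizes ``b``, the coupling vector and
        the target assignment — everything parameter-recovery tests need.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    alphas = config.alphas()
    genes = _gene_ids(config.n_genes)
    reg_names = config.regulator_names()

    # patients, groups, dropout
    n_mdd = int(round(config.frac_mdd * config.n_patients))
    width = max(2, len(str(config.n_patients)))
    patients = [f"P{i + 1:0{width}d}" for i in range(config.n_patients)]
    groups = {p: ("MDD" if i < n_mdd else "nonMDD") for i, p in enumerate(patients)}
    n_drop = int(round(config.dropout_frac * config.n_patients))
    n_drop_mdd = int(round(n_drop * n_mdd / config.n_patients)) if config.n_patients else 0
    n_drop_mdd = min(n_drop_mdd, n_mdd)
    n_drop_non = min(n_drop - n_drop_mdd, config.n_patients - n_mdd)
    mdd_patients = patients[:n_mdd]
    non_patients = patients[n_mdd:]
    dropped = set(rng.choice(mdd_patients, size=n_drop_mdd, replace=False)) | set(
        rng.choice(non_patients, size=n_drop_non, replace=False)
    )

    rows = []
    for p in patients:
        rows.append((f"{p}_baseline", p, groups[p], "baseline"))
        if p not in dropped:
            rows.append((f"{p}_post", p, groups[p], "post"))
    sample_ids = [r[0] for r in rows]

    # MADRS per group × timepoint, truncated at 0
    madrs = np.empty(len(rows))
    for (g, tp), (mean, sd) in config.madrs_params.items():
        idx = [i for i, r in enumerate(rows) if r[2] == g and r[3] == tp]
        if idx:
            madrs[idx] = _truncated_normal(rng, mean, sd, len(idx))

    zmadrs = (madrs - madrs.mean()) / madrs.std()

    # latent activations: coupling × standardized MADRS + unit noise
    latents = zmadrs[:, None] * alphas[None, :] + rng.standard_normal((len(rows), len(alphas)))

    targets = _assign_targets(config, rng)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)
    patient_offsets = rng.normal(0.0, config.patient_sd, size=(config.n_genes, config.n_patients))
    p_index = {p: i for i, p in enumerate(patients)}

    x = np.empty((config.n_genes, len(rows)))
    col_patient = np.array([p_index[r[1]] for r in rows])
    x[:] = baseline[:, None] + patient_offsets[:, col_patient]

    b = np.zeros(config.n_genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    for r, name in enumerate(reg_names):
        gi = np.array([gene_index[g] for g in targets[name]])
        b[gi] = rng.uniform(0.5, 1.5, size=gi.size)
        x[gi, :] += b[gi, None] * latents[None, :, r][0][None, :]

    x += rng.normal(0.0, config.noise_sd, size=x.shape)

    expr = ExpressionMatrix(pd.DataFrame(x, index=genes, columns=sample_ids))
    design = CohortDesign(
        pd.DataFrame(
            {
                "patient_id": [r[1] for r in rows],
                "group": [r[2] for r in rows],
                "timepoint": [r[3] for r in rows],
                "madrs": madrs,
                "age": np.round(np.clip(rng.normal(38.5, 11.7, len(rows)), 18, 65), 1),
                "sex": rng.choice(["F", "M"], size=len(rows), p=[0.9, 0.1]),
                "bmi": np.round(
                    np.where(
                        np.array([r[3] for r in rows]) == "baseline",
                        rng.normal(42.0, 5.1, len(rows)),
                        rng.normal(31.2, 5.4, len(rows)),
                    ),
                    2,
                ),
            },
            index=sample_ids,
        )
    )
    # a patient's age and sex are timepoint-invariant
    t = design.table
    base_rows = t[t["timepoint"] == "baseline"].set_index("patient_id")
    t["age"] = base_rows.loc[t["patient_id"], "age"].to_numpy()
    t["sex"] = base_rows.loc[t["patient_id"], "sex"].to_numpy()

    gene_sets = GeneSetCollection(
        sets={name: list(gs) for name, gs in targets.items()},
        descriptions={name: "synthetic targets" for name in targets},
        directions={name: {g: +1 for g in gs} for name, gs in targets.items()},
    )
    truth = {
        "latents": pd.DataFrame(latents, index=sample_ids, columns=reg_names),
        "b": pd.Series(b, index=genes),
        "coupling_alpha": pd.Series(alphas, index=reg_names),
        "targets": targets,
        "dropped_patients": sorted(dropped),
        "madrs": pd.Series(madrs, index=sample_ids),
    }
    return expr, design, gene_sets, truth


def simulate_reference(config: SimulationConfig) -> tuple[ExpressionMatrix, dict[str, list[str]]]:
    """Cell-type reference matrix (genes × cell types) with marker blocks.

    Each cell type's marker block sits ``marker_offset`` log2 units above
    the common baseline in that cell type only.  Returns the matrix and
    the marker assignment.
    """
    config.validate()
    blocks = _marker_blocks(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    genes = _gene_ids(config.n_genes)
    names = config.cell_type_names()
    base = rng.normal(config.baseline_mean, 0.25, size=config.n_genes)
    ref = np.tile(base[:, None], (1, len(names)))
    gene_index = {g: i for i, g in enumerate(genes)}
    for c, name in enumerate(names):
        gi = [gene_index[g] for g in blocks[name]]
        ref[gi, c] += config.marker_offset
    return ExpressionMatrix(pd.DataFrame(ref, index=genes, columns=names)), blocks
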