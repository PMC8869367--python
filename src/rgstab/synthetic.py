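"""Synthetic OpenArray-style Ct panels with known ground truth.

The generator draws each cell of a genes x samples Ct grid from the
additive model that all four stability algorithms implicitly assume::

    Ct[i, s] = baseline_i + offset_s + effect_i * treated(s) + eps[i, s]

with ``eps ~ Normal(0, noise_sd_i)`` (Gaussian on the Ct scale, i.e.
log-normal abundance), a per-sample RNA-input offset shared by all genes,
a per-gene treatment effect added in every non-control condition, and a
spike-in row ``spike_baseline + tech_offset_s`` tracking technical handling.
Values beyond the detection threshold are censored the way real exports
look: reported missing with probability one half, otherwise floored at the
detection limit, so both cleaning rules are exercised downstream.

:func:`default_panel_spec` encodes a 15-candidate, 3-donor, two-condition
EV-miRNA panel with designated stable / unstable / condition-shifted /
treatment-responsive genes and three near-limit genes that fail presence
filtering, leaving 12 analyzable candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import RgstabError
from .io import CtMatrix


@dataclass
class SyntheticSpec:
    """Parameters of the generative model; the seed fully determines output."""

    n_donors: int = 3
    conditions: tuple[str, ...] = ("CTRL", "SF")
    baseline: dict[str, float] = field(default_factory=dict)  # gene -> cycles
    noise_sd: dict[str, float] = field(default_factory=dict)  # gene -> cycles
    treatment_effect: dict[str, float] = field(default_factory=dict)  # gene -> cycles
    sample_offset_sd: float = 0.5  # RNA-input variation across samples
    spike_gene: str = "ath-miR-159a"
    spike_baseline: float = 14.0
    spike_offset_sd: float = 0.3  # technical handling variation on the spike
    censor_above: float = 27.0  # detection threshold
    detection_limit: float = 28.0
    seed: int = 0

    @property
    def gene_ids(self) -> list[str]:
        return list(self.baseline)

    @property
    def n_genes(self) -> int:
        return len(self.baseline)

    def validate(self) -> None:
        if not self.conditions:
            raise RgstabError("need at least one condition", code="BAD_SPEC")
        if self.n_donors < 1 or self.n_genes < 1:
            raise RgstabError("need at least one donor and one gene", code="BAD_SPEC")
        for g in self.gene_ids:
            if self.noise_sd.get(g, 0.0) < 0:
                raise RgstabError(f"negative noise SD for {g!r}", code="BAD_SPEC")
        if self.spike_gene in self.baseline:
            raise RgstabError("spike gene must not appear among candidates", code="BAD_SPEC")
        if not self.censor_above < self.detection_limit:
            raise RgstabError("censor_above must be below detection_limit", code="BAD_SPEC")


@dataclass
class SyntheticTruth:
    """Realized generator state for parameter-recovery tests."""

    noise_sd: dict[str, float]
    treatment_effect: dict[str, float]
    sample_offset: dict[str, float]  # realized per-sample RNA-input offsets
    spike_offset: dict[str, float]
    stable_gene: str  # argmin of noise_sd + |treatment_effect| (overall)
    stable_gene_within: str  # argmin of noise_sd (within any single condition)
    unstable_gene: str  # argmax of noise_sd + |treatment_effect|


def _sample_ids(spec: SyntheticSpec) -> list[tuple[str, str]]:
    """(sample_id, condition) pairs; ids are condition-initial + donor number."""
    out = []
    for cond in spec.conditions:
        prefix = cond[0].upper()
        for d in range(1, spec.n_donors + 1):
            out.append((f"{prefix}{d}", cond))
    return out


def generate(spec: SyntheticSpec) -> tuple[CtMatrix, SyntheticTruth]:
    """Draw one panel from the spec's generative model.

    The same seed always yields the same matrix.  Returns the matrix (with
    spike row and condition labels attached) and the realized ground truth.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genes = spec.gene_ids
    pairs = _sample_ids(spec)
    samples = [s for s, _ in pairs]
    control = spec.conditions[0]

    offsets = {s: rng.normal(0.0, spec.sample_offset_sd) for s in samples}
    noise = {g: spec.noise_sd.get(g, 0.0) for g in genes}
    effect = {g: spec.treatment_effect.get(g, 0.0) for g in genes}

    grid = np.empty((len(genes) + 1, len(samples)))
    for i, g in enumerate(genes):
        for j, (s, cond) in enumerate(pairs):
            mu = spec.baseline[g] + offsets[s] + (effect[g] if cond != control else 0.0)
            grid[i, j] = mu + rng.normal(0.0, noise[g])
    spike_offsets = {s: rng.normal(0.0, spec.spike_offset_sd) for s in samples}
    grid[-1] = [spec.spike_baseline + spike_offsets[s] for s in samples]

    # censor: above-threshold values reported missing half the time,
    # otherwise floored at the limit (both export styles occur in the wild)
    censored = grid > spec.censor_above
    drop = rng.random(grid.shape) < 0.5
    grid[censored & drop] = np.nan
    grid[censored & ~drop] = spec.detection_limit

    values = pd.DataFrame(grid, index=genes + [spec.spike_gene], columns=samples)
    matrix = CtMatrix(
        values=values,
        condition={s: c for s, c in pairs},
        spike_gene=spec.spike_gene,
        detection_limit=spec.detection_limit,
        detection_threshold=spec.censor_above,
    )
    score = {g: noise[g] + abs(effect[g]) for g in genes}
    truth = SyntheticTruth(
        noise_sd=noise,
        treatment_effect=effect,
        sample_offset=offsets,
        spike_offset=spike_offsets,
        stable_gene=min(score, key=score.get),
        stable_gene_within=min(noise, key=noise.get),
        unstable_gene=max(score, key=score.get),
    )
    return matrix, truth


# -- default panel ----------------------------------------------------------

#: Designated roles in the default 15-candidate panel.
STABLE_GENE = "miR-24-3p"  # near-zero noise, no treatment response
UNSTABLE_GENE = "miR-34a-5p"  # large biological + technical noise
CONDITION_SHIFTED_GENE = "miR-23a-3p"  # tight within conditions, shifted by treatment
TARGET_GENE = "miR-193b-5p"  # treatment-responsive target (2-fold up, -1 cycle)
NEAR_LIMIT_GENES = ("miR-22-5p", "miR-29a-5p", "miR-101-3p")  # fail presence filter


def default_panel_spec(seed: int = 0) -> SyntheticSpec:
    """The default 15-candidate EV-miRNA panel: 3 donors x {CTRL, SF}.

    Roles: one designated stable gene (SD 0.05 cycles, no treatment effect),
    one unstable gene (SD 1.5 cycles, the scale of a reference gene one
    should never use), one gene stable within each condition but
    shifted +1.2 cycles by treatment (stable per condition, unreliable
    overall — clearly outside the top ranks in the merged analysis yet well
    separated from the unstable gene's designated last place),
    one treatment-responsive target (-1 cycle in the treated condition,
    i.e. a 2-fold increase), three genes sitting at the detection limit
    (baseline 27.5) that presence filtering removes, and eight fillers with
    noise SDs 0.30-0.80 cycles spanning ordinary candidate quality.
    Baselines span the 12-26 cycle range of real panels.
    """
    baseline = {
        STABLE_GENE: 17.0,
        UNSTABLE_GENE: 22.0,
        CONDITION_SHIFTED_GENE: 19.0,
        TARGET_GENE: 23.0,
        "miR-16-5p": 14.0,
        "miR-425-5p": 20.5,
        "miR-660-5p": 18.5,
        "U6 snRNA": 16.0,
        "miR-423-5p": 21.5,
        "miR-26a-5p": 15.5,
        "miR-221-3p": 24.0,
        "miR-103a-3p": 25.5,
        NEAR_LIMIT_GENES[0]: 27.5,
        NEAR_LIMIT_GENES[1]: 27.5,
        NEAR_LIMIT_GENES[2]: 27.5,
    }
    noise_sd = {
        STABLE_GENE: 0.05,
        UNSTABLE_GENE: 1.5,
        CONDITION_SHIFTED_GENE: 0.10,
        TARGET_GENE: 0.12,
        "miR-16-5p": 0.30,
        "miR-425-5p": 0.35,
        "miR-660-5p": 0.40,
        "U6 snRNA": 0.45,
        "miR-423-5p": 0.50,
        "miR-26a-5p": 0.60,
        "miR-221-3p": 0.70,
        "miR-103a-3p": 0.80,
        NEAR_LIMIT_GENES[0]: 0.5,
        NEAR_LIMIT_GENES[1]: 0.5,
        NEAR_LIMIT_GENES[2]: 0.5,
    }
    treatment_effect = {
        CONDITION_SHIFTED_GENE: 1.2,
        TARGET_GENE: -1.0,  # one cycle earlier = doubled abundance
    }
    return SyntheticSpec(
        n_donors=3,
        conditions=("CTRL", "SF"),
        baseline=baseline,
        noise_sd=noise_sd,
        treatment_effect=treatment_effect,
        sample_offset_sd=0.5,
        spike_offset_sd=0.3,
        seed=seed,
    )
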