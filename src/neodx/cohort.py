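"""Synthetic dried-blood-spot cohorts.

The generator emulates the statistical structure the downstream stages
assume, so the whole pipeline is testable without any measured data:

* concentrations are log-normal around per-analyte baseline medians
  (µmol/L) — positive, right-skewed, and monotone-equivalent to whatever
  the true marginals are, which is all the rank-based stages can see;
* group effects are multiplicative shifts of the median (fold-changes),
  matching how screening studies report direction and magnitude;
* inter-analyte dependence is a block-correlation structure on the log
  scale (within-class blocks by default), optionally rewired per group so
  the differential-correlation stage has structure to find.

Effect directions in the shipped scenarios follow the experimental rat
designs they emulate (hypoxia–ischemia time course, LPS inflammation ±
hypoxia–ischemia, therapeutic hypothermia); the magnitudes are stand-ins
— the underlying study reports directions and significance, not effect
sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SampleTable
from .panel import MetabolitePanel, default_panel

__all__ = [
    "GroupSpec",
    "EffectTemplate",
    "NoiseModel",
    "generate_cohort",
    "scenario_library",
    "Scenario",
]


@dataclass(frozen=True)
class GroupSpec:
    """One experimental arm: label, size, sampling time and fold-changes."""

    label: str
    n: int
    time_h: float | None = None
    treatment: str = "none"
    fold: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group {self.label!r}: size must be >= 2")
        for code, f in self.fold.items():
            if not f > 0:
                raise ValueError(
                    f"group {self.label!r}: fold-change for {code!r} "
                    f"must be > 0, got {f}"
                )

    def direction(self, code: str) -> str:
        f = self.fold.get(code, 1.0)
        return "up" if f > 1 else ("down" if f < 1 else "none")


@dataclass(frozen=True)
class EffectTemplate:
    """Scenario design: named groups with per-analyte fold-changes.

    ``correlation_overrides`` maps a group label to a block specification
    (same format as :class:`NoiseModel.blocks`) replacing the noise
    model's default blocks for that group — this is how differential
    correlation ("rewiring") between two arms is planted.
    """

    name: str
    groups: tuple[GroupSpec, ...]
    correlation_overrides: dict[str, list[tuple[list[str], float]]] = field(
        default_factory=dict
    )

    def group(self, label: str) -> GroupSpec:
        for g in self.groups:
            if g.label == label:
                return g
        raise KeyError(f"no group {label!r} in scenario {self.name!r}")


@dataclass(frozen=True)
class NoiseModel:
    """Log-normal marginals plus block correlation on the log scale.

    ``baseline`` maps analyte code → median concentration (µmol/L);
    ``sdlog`` is the common log-scale SD (per-analyte overrides via
    ``sdlog_per_analyte``); ``blocks`` is a list of
    ``(analyte codes, rho)`` with a common within-block correlation.
    """

    baseline: dict[str, float]
    sdlog: float = 0.3
    sdlog_per_analyte: dict[str, float] = field(default_factory=dict)
    blocks: list[tuple[list[str], float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sdlog > 0:
            raise ValueError("sdlog must be > 0")
        for code, s in self.sdlog_per_analyte.items():
            if not s > 0:
                raise ValueError(f"sdlog for {code!r} must be > 0")
        for codes, rho in self.blocks:
            if not -1 < rho < 1:
                raise ValueError(f"block rho must be in (-1, 1), got {rho}")

    def sd_vector(self, codes: list[str]) -> np.ndarray:
        return np.array(
            [self.sdlog_per_analyte.get(c, self.sdlog) for c in codes]
        )

    def correlation_matrix(
        self,
        codes: list[str],
        blocks: list[tuple[list[str], float]] | None = None,
    ) -> np.ndarray:
        """Assemble the block-correlation matrix and check it is PSD."""
        blocks = self.blocks if blocks is None else blocks
        idx = {c: i for i, c in enumerate(codes)}
        R = np.eye(len(codes))
        for members, rho in blocks:
            ii = [idx[c] for c in members if c in idx]
            for a in ii:
                for b in ii:
                    if a != b:
                        R[a, b] = rho
        eigmin = np.linalg.eigvalsh(R).min()
        if eigmin < -1e-10:
            raise ValueError(
                f"correlation structure is not positive semi-definite "
                f"(min eigenvalue {eigmin:.3g})"
            )
        return R


def generate_cohort(
    template: EffectTemplate,
    noise: NoiseModel,
    seed: int,
    panel: MetabolitePanel | None = None,
) -> SampleTable:
    """Draw one synthetic cohort; deterministic per ``seed``.

    Each sample is ``exp(log median + log fold + L·z ⊙ sd)`` with ``z``
    standard normal and ``L`` the Cholesky factor of the group's
    correlation matrix, so group medians are ``baseline × fold`` and the
    planted Spearman correlation approaches the specified block ``rho``.
    """
    panel = panel or default_panel()
    codes = panel.codes
    missing = [c for c in codes if c not in noise.baseline]
    if missing:
        raise ValueError(f"noise model lacks baselines for: {missing[:5]}")
    rng = np.random.default_rng(seed)
    sd = noise.sd_vector(codes)
    log_base = np.log(np.array([noise.baseline[c] for c in codes]))

    rows, ids, meta_rows = [], [], []
    for g in template.groups:
        blocks = template.correlation_overrides.get(g.label)
        L = np.linalg.cholesky(
            noise.correlation_matrix(codes, blocks)
            + 1e-12 * np.eye(len(codes))
        )
        log_fold = np.log(
            np.array([g.fold.get(c, 1.0) for c in codes])
        )
        z = rng.standard_normal((g.n, len(codes)))
        logx = log_base + log_fold + (z @ L.T) * sd
        rows.append(np.exp(logx))
        ids.extend(f"{g.label}_{i+1:03d}" for i in range(g.n))
        meta_rows.extend(
            {"group": g.label, "time_h": g.time_h, "treatment": g.treatment}
            for _ in range(g.n)
        )
    data = pd.DataFrame(np.vstack(rows), index=pd.Index(ids, name="sample_id"),
                        columns=codes)
    meta = pd.DataFrame(meta_rows, index=data.index)
    return SampleTable(panel, data, meta)


# ---------------------------------------------------------------------------
# Baseline medians (µmol/L).  Typical dried-blood-spot screening levels:
# amino acids tens–hundreds, free/short-chain carnitines tens, long-chain
# carnitines well below 1, nucleosides and succinylacetone ~1 or less.
# ---------------------------------------------------------------------------

_BASELINES: dict[str, float] = {
    "Gly": 400.0, "Ala": 300.0, "Val": 150.0, "Leu/Ile/Hyp": 180.0,
    "Met": 30.0, "Phe": 60.0, "Tyr": 70.0, "Orn": 100.0, "Cit": 15.0,
    "Glu": 250.0, "Gln/Lys": 450.0, "Arg": 20.0, "ASA": 1.0, "Pro": 180.0,
    "C0": 25.0, "C2": 20.0, "C3": 2.0, "C3DC/C4OH": 0.15, "C4": 0.4,
    "C4DC/C5OH": 0.25, "C5": 0.15, "C5:1": 0.05, "C5DC/C6OH": 0.1,
    "C6": 0.08, "C6DC": 0.06, "C8": 0.1, "C8:1": 0.12, "C10": 0.12,
    "C10:1": 0.1, "C10:2": 0.04, "C12": 0.1, "C12:1": 0.1, "C14": 0.25,
    "C14:1": 0.12, "C14:2": 0.05, "C14OH": 0.03, "C16": 3.0, "C16:1": 0.25,
    "C16OH": 0.03, "C16:1OH": 0.04, "C18": 1.0, "C18:1": 1.2, "C18:2": 0.4,
    "C18OH": 0.02, "C18:1OH": 0.03, "C18:2OH": 0.02, "C20": 0.05,
    "C22": 0.04, "C24": 0.04, "C26": 0.02,
    "Ado": 1.0, "d-Ado": 0.5,
    "SA": 1.0,
    "LPC C20:0": 1.5, "LPC C22:0": 1.0, "LPC C24:0": 0.8, "LPC C26:0": 0.5,
}

# Acylcarnitines flagged as rising after hypoxia–ischemia, with the 3 h
# (early, weaker) and 6 h (established) fold-changes used by the scenarios.
_HIE3_UP = ["C3DC/C4OH", "C5DC/C6OH", "C10:2", "C26", "C18:2", "C14",
            "C24", "C3"]
_HIE6_UP = ["C26", "C3DC/C4OH", "C3", "C4", "C18:2", "C2", "C5DC/C6OH",
            "C24", "C8:1", "C20", "C5", "C10:2"]


def _default_blocks(panel: MetabolitePanel) -> list[tuple[list[str], float]]:
    """Within-class correlation blocks (rho=0.4) for the major classes."""
    return [
        (panel.codes_of_class("amino_acid"), 0.4),
        (panel.codes_of_class("acylcarnitine"), 0.4),
        (panel.codes_of_class("lysophosphatidylcholine"), 0.4),
    ]


@dataclass(frozen=True)
class Scenario:
    """An effect template paired with the noise model that realises it."""

    template: EffectTemplate
    noise: NoiseModel

    def generate(self, seed: int,
                 panel: MetabolitePanel | None = None) -> SampleTable:
        return generate_cohort(self.template, self.noise, seed, panel)


def scenario_library(
    panel: MetabolitePanel | None = None,
) -> dict[str, Scenario]:
    """The shipped study designs.

    ``hie_timecourse``
        control (0 h, n=10) vs 3 h (n=13) vs 6 h (n=12) after
        hypoxia–ischemia: glycine up at 3 h (fold 1.5) and more at 6 h
        (2.0); methionine down at 6 h (0.7); succinylacetone and the
        listed acylcarnitines up; deoxyadenosine down.
    ``lps_vs_lps_hie``
        control (n=11), LPS inflammation (n=11), LPS+HIE (n=27):
        short-chain acylcarnitines C4/C5/C5DC/C6OH/C8:1 rise under
        inflammation but fall when hypoxia–ischemia is superimposed;
        glycine/alanine/ASA up and methionine, LPC C26:0, C8, C14:1 down
        in LPS+HIE; two correlation blocks are rewired between the LPS
        and LPS+HIE arms (amino-acid block tight under LPS alone,
        short-chain-acylcarnitine block tight under LPS+HIE).
    ``th_vs_normothermia``
        control (n=13), HIE+hypothermia (n=16), HIE normothermia (n=14):
        normothermic HIE shows the 6 h profile; under hypothermia
        ornithine/valine/Leu-Ile-Hyp are higher and the LPCs plus C26,
        C5DC/C6OH, C6, C14:2 lower than under normothermia.
    ``validation_pool``
        the pooled 6 h validation design: controls (n=23) vs 6 h
        hypoxia–ischemia (n=26) from the first and third experiments
        combined, for repeated train/test split validation.
    ``null``
        three groups with no effects (all fold-changes 1.0).
    """
    panel = panel or default_panel()
    noise = NoiseModel(baseline=dict(_BASELINES),
                       sdlog=0.3, blocks=_default_blocks(panel))

    hie3 = {"Gly": 1.5, "Gln/Lys": 1.25, "d-Ado": 0.75}
    hie3.update({c: 1.4 for c in _HIE3_UP})
    hie6 = {"Gly": 2.0, "Met": 0.7, "SA": 1.5, "d-Ado": 0.75}
    hie6.update({c: 1.5 for c in _HIE6_UP})
    hie_timecourse = EffectTemplate(
        "hie_timecourse",
        (
            GroupSpec("control", 10, time_h=0.0),
            GroupSpec("hie_3h", 13, time_h=3.0, treatment="HIE", fold=hie3),
            GroupSpec("hie_6h", 12, time_h=6.0, treatment="HIE", fold=hie6),
        ),
    )

    short_chain = ["C4", "C5", "C5DC/C6OH", "C8:1"]
    lps_fold = {c: 1.5 for c in short_chain}
    lps_hie_fold = {
        "ASA": 1.8, "Gly": 1.8, "Ala": 1.5, "C5:1": 1.5,
        "C3DC/C4OH": 1.5, "C18": 1.4,
        "Met": 0.7, "LPC C26:0": 0.7, "C8": 0.7, "C14:1": 0.7,
    }
    lps_hie_fold.update({c: 0.6 for c in short_chain})
    aa_block = ["Gly", "Ala", "Met", "Phe", "Tyr", "Orn", "Cit", "Glu"]
    sc_block = ["C4", "C5", "C5DC/C6OH", "C8:1", "C6", "C8", "C3", "C2"]
    lps_vs_lps_hie = EffectTemplate(
        "lps_vs_lps_hie",
        (
            GroupSpec("control", 11),
            GroupSpec("lps", 11, time_h=6.0, treatment="LPS", fold=lps_fold),
            GroupSpec("lps_hie", 27, time_h=6.0, treatment="LPS+HIE",
                      fold=lps_hie_fold),
        ),
        correlation_overrides={
            "lps": [(aa_block, 0.7), (sc_block, 0.1)],
            "lps_hie": [(aa_block, 0.1), (sc_block, 0.7)],
        },
    )

    th_fold = dict(hie6)
    th_fold.update({
        "Orn": 1.4, "Val": 1.4, "Leu/Ile/Hyp": 1.4,
        "LPC C20:0": 0.7, "LPC C22:0": 0.7, "LPC C24:0": 0.7,
        "LPC C26:0": 0.7,
        "C26": 1.0, "C5DC/C6OH": 1.0, "C6": 0.7, "C14:2": 0.7,
        "Gly": 1.6,
    })
    th_vs_normothermia = EffectTemplate(
        "th_vs_normothermia",
        (
            GroupSpec("control", 13),
            GroupSpec("hie_th", 16, time_h=6.0, treatment="HIE+TH",
                      fold=th_fold),
            GroupSpec("hie_nt", 14, time_h=6.0, treatment="HIE", fold=hie6),
        ),
    )

    # Pooled 6 h validation set: controls and 6 h hypoxia–ischemia arms
    # from the time-course and hypothermia designs together (10+13 vs
    # 12+14).  In the generator both experiments share the same
    # distributions, so the pool is realized as one two-arm design.
    validation_pool = EffectTemplate(
        "validation_pool",
        (
            GroupSpec("control", 23),
            GroupSpec("hie_6h", 26, time_h=6.0, treatment="HIE", fold=hie6),
        ),
    )

    null = EffectTemplate(
        "null",
        (
            GroupSpec("g1", 10, time_h=0.0),
            GroupSpec("g2", 13, time_h=3.0),
            GroupSpec("g3", 12, time_h=6.0),
        ),
    )

    return {
        "hie_timecourse": Scenario(hie_timecourse, noise),
        "lps_vs_lps_hie": Scenario(lps_vs_lps_hie, noise),
        "th_vs_normothermia": Scenario(th_vs_normothermia, noise),
        "validation_pool": Scenario(validation_pool, noise),
        "null": Scenario(null, noise),
    }
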