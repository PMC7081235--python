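"""Synthetic count experiments with planted structure and known ground truth.

The generator emulates the study design the pipeline targets: five genotypes
(a wild type plus four regulator mutants), three stress experiments each
sampled at control / early / late time-points, and four biological replicates
per cell.  Counts are negative-binomial with per-gene baseline abundances and
dispersions; structure is planted at four levels:

* **Common stress regulons** — four disjoint gene sets (EARLY/LATE × UP/DOWN)
  carrying a ±``lfc_effect`` log2 fold-change in *all three* stresses at the
  designated phase, in every genotype unless overridden below.
* **Stress-specific responders** — genes responding in a single stress only,
  so that cross-stress intersection is a real filter and not a no-op.
* **Mutant non-responsiveness** — per mutant, a fraction of the EARLY UP
  regulon fails to respond, by one of two mechanisms: *loss of activation*
  (LA: wild-type-like control level, no stress induction) or *loss of
  repression* (LR: de-repressed at control by +``lfc_effect`` and already at
  the wild-type stressed level, hence no further induction).
* **TF target maps and network modules** — TF target sets concentrated in a
  designated regulon, and a gene → module partition concentrating each
  regulon in one module.

Every random draw flows from one global seed through independent named
substreams, so fixtures are reproducible and any single stage can be varied
in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    AnnotationMap,
    CountExperiment,
    write_counts,
    write_design,
    write_gmt,
)

REGULON_NAMES = ("early_up", "early_down", "late_up", "late_down")

_DEFAULT_GENOTYPES = ("col0", "med9", "med16", "med18", "cdk8")
_DEFAULT_STRESSES = ("heat", "cold", "salt")
_DEFAULT_FAMILIES = ("WRKY", "HSF", "CAMTA", "ERF", "NAC", "bZIP", "MYB", "DOF")

# Which regulon each TF family's targets concentrate in.  The first families
# are early responders, later ones late, mirroring the wave structure the
# enrichment stage is meant to recover.  ``None`` marks null families whose
# targets are uniform.
_FAMILY_REGULON = {
    "WRKY": "early_up",
    "HSF": "early_up",
    "CAMTA": "early_up",
    "ERF": "late_up",
    "NAC": "late_up",
    "bZIP": "early_down",
    "MYB": "late_down",
    "DOF": None,
}


class ConfigError(ValueError):
    """Infeasible simulation configuration."""


@dataclass
class SimConfig:
    """Parameters of the synthetic experiment.

    Defaults are the small desk-scale preset: 2,000 genes, 50 genes per
    planted regulon, log2 effect 2, four replicates, a mean depth of 150
    reads per gene, and mutant non-responsive/LR fractions giving one
    LR-dominant genotype (med16) against an LA-dominant background.
    """

    n_genes: int = 2000
    genotypes: tuple[str, ...] = _DEFAULT_GENOTYPES
    wild_type: str = "col0"
    stresses: tuple[str, ...] = _DEFAULT_STRESSES
    n_reps: int = 4
    depth_mean: float = 5e6
    # per-gene baseline: exp(Normal(mu, sd)) rescaled so the expected library
    # totals depth_mean
    baseline_log_mean: float = 4.7
    baseline_log_sd: float = 1.3
    # per-gene NB dispersion: log-normal, clipped to a realistic bulk range;
    # median 0.04 matches typical gene-wise bulk RNA-seq estimates at 4 reps
    dispersion_log_mean: float = float(np.log(0.04))
    dispersion_log_sd: float = 1.0
    dispersion_range: tuple[float, float] = (0.01, 1.0)
    # library size factors drawn uniform in this range of depth_mean
    library_factor_range: tuple[float, float] = (0.7, 1.3)
    lfc_effect: float = 2.0
    n_common_up_early: int = 50
    n_common_down_early: int = 50
    n_common_up_late: int = 50
    n_common_down_late: int = 50
    n_stress_specific: int = 30  # per stress, early up, one stress only
    fraction_nonresponsive: Mapping[str, float] = field(
        default_factory=lambda: {"med9": 0.30, "med16": 0.50,
                                 "med18": 0.25, "cdk8": 0.30})
    fraction_lr: Mapping[str, float] = field(
        default_factory=lambda: {"med9": 0.12, "med16": 0.50,
                                 "med18": 0.12, "cdk8": 0.12})
    n_tfs: int = 40
    families: tuple[str, ...] = _DEFAULT_FAMILIES
    targets_per_tf: int = 40
    enrichment_concentration: float = 0.8
    n_modules: int = 8
    module_concentration: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        planted = (self.n_common_up_early + self.n_common_down_early
                   + self.n_common_up_late + self.n_common_down_late
                   + self.n_stress_specific * len(self.stresses))
        if planted > self.n_genes:
            raise ConfigError(
                f"planted sets ({planted}) exceed n_genes ({self.n_genes})")
        if self.n_reps < 2:
            raise ConfigError("n_reps must be >= 2")
        if self.wild_type not in self.genotypes:
            raise ConfigError(f"wild type {self.wild_type!r} not in genotypes")
        for name, frac in list(self.fraction_nonresponsive.items()) + list(
                self.fraction_lr.items()):
            if not 0.0 <= frac <= 1.0:
                raise ConfigError(f"fraction for {name!r} outside [0, 1]")
        if self.targets_per_tf > self.n_genes:
            raise ConfigError("targets_per_tf exceeds n_genes")
        if self.n_modules < 1:
            raise ConfigError("n_modules must be >= 1")

    @property
    def mutants(self) -> tuple[str, ...]:
        return tuple(g for g in self.genotypes if g != self.wild_type)


@dataclass
class GroundTruth:
    """Planted structure of a simulated experiment."""

    regulon: dict[str, str]            # gene -> regulon name (common regulons)
    stress_specific: dict[str, str]    # gene -> stress (early-up, one stress)
    mechanism: dict[str, dict[str, str]]  # mutant -> gene -> "LR" | "LA"
    tf_family: dict[str, str]
    tf_regulon: dict[str, str | None]
    module_of: dict[str, str]
    baseline_mean: dict[str, float]
    dispersion: dict[str, float]
    library_factors: dict[str, float]
    lfc_effect: float

    def regulon_genes(self, name: str) -> frozenset[str]:
        return frozenset(g for g, r in self.regulon.items() if r == name)

    def mechanism_of(self, mutant: str, gene: str) -> str:
        return self.mechanism.get(mutant, {}).get(gene, "responsive")

    def nonresponsive_genes(self, mutant: str) -> frozenset[str]:
        return frozenset(self.mechanism.get(mutant, {}))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


def _streams(seed: int, names: Sequence[str]) -> dict[str, np.random.Generator]:
    seqs = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, seqs)}


def simulate_experiment(config: SimConfig) -> tuple[CountExperiment, GroundTruth]:
    """Draw a count experiment and its ground truth from ``config``.

    Counts are NB with mean = library factor × per-gene baseline ×
    2^(planted log2 effect) and per-gene dispersion.  The same seed always
    yields the same matrices.
    """
    config.validate()
    rng = _streams(config.seed, ["baseline", "dispersion", "library",
                                 "plant", "counts", "tf", "modules"])

    genes = [f"g{i:05d}" for i in range(config.n_genes)]

    # per-gene baseline abundance, rescaled to the target depth
    q = np.exp(rng["baseline"].normal(config.baseline_log_mean,
                                      config.baseline_log_sd, config.n_genes))
    q *= config.depth_mean / q.sum()
    alpha = np.exp(rng["dispersion"].normal(config.dispersion_log_mean,
                                            config.dispersion_log_sd,
                                            config.n_genes))
    alpha = np.clip(alpha, *config.dispersion_range)

    # ----- plant gene sets ------------------------------------------------
    plant = rng["plant"]
    sizes = [config.n_common_up_early, config.n_common_down_early,
             config.n_common_up_late, config.n_common_down_late]
    n_spec_total = config.n_stress_specific * len(config.stresses)
    chosen = plant.choice(config.n_genes, size=sum(sizes) + n_spec_total,
                          replace=False)
    regulon: dict[str, str] = {}
    offset = 0
    regulon_idx: dict[str, np.ndarray] = {}
    for name, size in zip(REGULON_NAMES, sizes):
        idx = chosen[offset:offset + size]
        offset += size
        regulon_idx[name] = idx
        for i in idx:
            regulon[genes[i]] = name
    stress_specific: dict[str, str] = {}
    spec_idx: dict[str, np.ndarray] = {}
    for stress in config.stresses:
        idx = chosen[offset:offset + config.n_stress_specific]
        offset += config.n_stress_specific
        spec_idx[stress] = idx
        for i in idx:
            stress_specific[genes[i]] = stress

    # per-mutant non-responsive genes out of EARLY UP, split into LR / LA
    mechanism: dict[str, dict[str, str]] = {}
    eu_idx = regulon_idx["early_up"]
    for mutant in config.mutants:
        frac_nr = float(config.fraction_nonresponsive.get(mutant, 0.0))
        n_nr = int(round(frac_nr * len(eu_idx)))
        nr = plant.choice(eu_idx, size=n_nr, replace=False)
        frac_lr = float(config.fraction_lr.get(mutant, 0.0))
        n_lr = int(round(frac_lr * n_nr))
        lr = set(nr[:n_lr].tolist())
        mechanism[mutant] = {
            genes[i]: ("LR" if i in lr else "LA") for i in nr
        }

    # ----- build the sample grid and the log2-effect tensor ---------------
    samples: list[str] = []
    design_rows = []
    for genotype in config.genotypes:
        for stress in config.stresses:
            for timepoint in ("control", "early", "late"):
                for rep in range(1, config.n_reps + 1):
                    samples.append(f"{genotype}_{stress}_{timepoint}_{rep}")
                    design_rows.append((genotype, stress, timepoint, rep))
    design = pd.DataFrame(design_rows, index=samples,
                          columns=["genotype", "stress", "timepoint", "replicate"])

    n_samples = len(samples)
    delta = np.zeros((config.n_genes, n_samples))
    genotype_arr = design["genotype"].to_numpy()
    stress_arr = design["stress"].to_numpy()
    tp_arr = design["timepoint"].to_numpy()
    e = config.lfc_effect

    # common regulons: effect in every stress at the designated phase
    phase_sign = {"early_up": ("early", +e), "early_down": ("early", -e),
                  "late_up": ("late", +e), "late_down": ("late", -e)}
    for name, (phase, eff) in phase_sign.items():
        cols = tp_arr == phase
        delta[np.ix_(regulon_idx[name], cols)] += eff

    # stress-specific early-up responders
    for stress, idx in spec_idx.items():
        cols = (tp_arr == "early") & (stress_arr == stress)
        delta[np.ix_(idx, cols)] += e

    # mutant non-responsiveness (EARLY UP only)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for mutant, mechs in mechanism.items():
        gcols = genotype_arr == mutant
        la_rows = [gene_pos[g] for g, m in mechs.items() if m == "LA"]
        lr_rows = [gene_pos[g] for g, m in mechs.items() if m == "LR"]
        if la_rows:
            # loss of activation: cancel the early induction in this mutant
            delta[np.ix_(la_rows, gcols & (tp_arr == "early"))] -= e
        if lr_rows:
            # loss of repression: de-repressed at control, already at the
            # wild-type stressed level (early/control ratio 1)
            delta[np.ix_(lr_rows, gcols & (tp_arr == "control"))] += e

    # ----- draw the counts -------------------------------------------------
    lo, hi = config.library_factor_range
    lib = rng["library"].uniform(lo, hi, n_samples)
    mu = lib[None, :] * q[:, None] * np.exp2(delta)
    n_param = 1.0 / alpha[:, None]
    p_param = n_param / (n_param + mu)
    counts = rng["counts"].negative_binomial(n_param, p_param).astype(np.int64)

    experiment = CountExperiment(genes=genes, samples=samples,
                                 counts=counts, design=design)
    truth = GroundTruth(
        regulon=regulon,
        stress_specific=stress_specific,
        mechanism=mechanism,
        tf_family={},
        tf_regulon={},
        module_of={},
        baseline_mean=dict(zip(genes, q.tolist())),
        dispersion=dict(zip(genes, alpha.tolist())),
        library_factors=dict(zip(samples, lib.tolist())),
        lfc_effect=config.lfc_effect,
    )
    return experiment, truth


def make_binding_map(config: SimConfig, truth: GroundTruth) -> AnnotationMap:
    """Draw a TF → target-gene map with targets concentrated in regulons.

    Each TF belongs to a family; each family is tied to one regulon (or to
    none, for null families).  A target is drawn from the TF's regulon with
    probability ``enrichment_concentration`` and uniformly from the rest of
    the gene universe otherwise.  Updates ``truth.tf_family`` /
    ``truth.tf_regulon`` in place and returns the map.
    """
    config.validate()
    rng = _streams(config.seed, ["baseline", "dispersion", "library",
                                 "plant", "counts", "tf", "modules"])["tf"]
    genes = np.array(sorted(truth.baseline_mean))
    gene_pos = {g: i for i, g in enumerate(genes)}

    targets: dict[str, frozenset[str]] = {}
    family_map: dict[str, str] = {}
    for t in range(config.n_tfs):
        fam = config.families[t % len(config.families)]
        tf = f"{fam}{t + 1:02d}"
        reg_name = _FAMILY_REGULON.get(fam)
        pool = (np.array([gene_pos[g] for g in truth.regulon_genes(reg_name)])
                if reg_name else np.array([], dtype=int))
        k = rng.binomial(config.targets_per_tf, config.enrichment_concentration)
        k = min(k, len(pool)) if len(pool) else 0
        inside = rng.choice(pool, size=k, replace=False) if k else np.array([], dtype=int)
        outside_pool = np.setdiff1d(np.arange(len(genes)), pool, assume_unique=False)
        outside = rng.choice(outside_pool, size=config.targets_per_tf - k,
                             replace=False)
        tf_targets = frozenset(genes[np.concatenate([inside, outside])].tolist())
        targets[tf] = tf_targets
        family_map[tf] = fam
        truth.tf_family[tf] = fam
        truth.tf_regulon[tf] = reg_name
    return AnnotationMap(targets=targets, family=family_map)


def make_modules(config: SimConfig, truth: GroundTruth) -> pd.DataFrame:
    """Assign every gene to exactly one module.

    Each planted regulon is concentrated in one designated module with
    probability ``module_concentration`` per gene; all remaining genes are
    assigned uniformly.  Returns a gene → module table and records the
    assignment in ``truth.module_of``.
    """
    config.validate()
    rng = _streams(config.seed, ["baseline", "dispersion", "library",
                                 "plant", "counts", "tf", "modules"])["modules"]
    genes = sorted(truth.baseline_mean)
    modules = [f"M{i + 1}" for i in range(config.n_modules)]
    designated = {name: modules[i % len(modules)]
                  for i, name in enumerate(REGULON_NAMES)}
    assignment: dict[str, str] = {}
    for g in genes:
        reg = truth.regulon.get(g)
        if reg is not None and rng.random() < config.module_concentration:
            assignment[g] = designated[reg]
        else:
            assignment[g] = modules[rng.integers(len(modules))]
    truth.module_of.update(assignment)
    return pd.DataFrame({"gene": genes,
                         "module": [assignment[g] for g in genes]})


def write_fixture(experiment: CountExperiment, truth: GroundTruth,
                  binding_map: AnnotationMap, modules: pd.DataFrame,
                  out_dir: str | Path) -> dict[str, Path]:
    """Emit the full fixture: counts, design, GMT, family TSV, module TSV, truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.tsv",
        "design": out / "design.tsv",
        "gmt": out / "tf_targets.gmt",
        "family": out / "tf_families.tsv",
        "modules": out / "modules.tsv",
        "truth": out / "truth.json",
    }
    write_counts(experiment, paths["counts"])
    write_design(experiment.design, paths["design"])
    write_gmt(binding_map, paths["gmt"])
    pd.DataFrame({"tf": list(binding_map.family),
                  "family": list(binding_map.family.values())}
                 ).to_csv(paths["family"], sep="\t", index=False)
    modules.to_csv(paths["modules"], sep="\t", index=False)
    truth.to_json(paths["truth"])
    return paths


def small_config(seed: int = 0, **overrides) -> SimConfig:
    """The desk-scale preset (2,000 genes); full pipeline in well under 2 min."""
    return SimConfig(seed=seed, **overrides)


def paper_scale_config(seed: int = 0, **overrides) -> SimConfig:
    """A preset at the scale of a real experiment (heavy; not used by tests)."""
    defaults = dict(
        n_genes=24_000,
        depth_mean=1.6e7,
        n_common_up_early=281, n_common_down_early=349,
        n_common_up_late=268, n_common_down_late=574,
        n_stress_specific=1500,
        n_tfs=200, targets_per_tf=100, n_modules=40,
    )
    defaults.update(overrides)
    return SimConfig(seed=seed, **defaults)
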