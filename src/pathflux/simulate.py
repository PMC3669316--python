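"""Synthetic two-class microarray studies and assay plates.

The generator emulates the statistical structure the analysis assumes, so
the whole pipeline is testable without any download: a log2-intensity
probeset matrix with multiple probesets per gene and isozyme genes sharing
an EC number, a layered annotation map, a pathway catalog partitioning the
EC pool, planted coordinated expression shifts in designated pathways (a
known truth table), and plate data in which lactate production rises and
oxygen consumption falls with drug dose while cell counts follow
exponential growth.

Everything is driven by one :class:`numpy.random.Generator` seeded from the
config, so a fixed seed reproduces every output bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .annotation import EnzymeMap
from .assays import AssayPlate
from .enrichment import PathwayCatalog, build_catalog
from .io import ExpressionStudy

__all__ = [
    "PlantedEffect",
    "AssayConfig",
    "SimulationConfig",
    "simulate_expression",
    "simulate_assay_plate",
]


@dataclass(frozen=True)
class PlantedEffect:
    """A coordinated shift planted in one pathway.

    ``delta`` is the mean shift of every member gene in the treated class,
    in units of the per-sample noise SD; ``direction`` is +1 (up in
    treatment) or -1.
    """

    pathway: str
    delta: float
    direction: int = 1

    def __post_init__(self):
        if self.direction not in (1, -1):
            raise ValueError("direction must be +1 or -1")
        if self.delta < 0:
            raise ValueError("delta must be >= 0; use direction for sign")


@dataclass(frozen=True)
class AssayConfig:
    """Plate-simulation block: doses, growth, rate dose-responses, noise.

    Rates are linear in dose: e.g. lactate production at dose d is
    ``lactate_rate0 + lactate_slope * d`` (nmol/h per 1e6 cells).  Defaults
    describe a cultured epithelial line shifting toward glycolysis: a
    rising lactate slope, a falling oxygen-consumption slope, and growth
    slowing with dose.  Glucose consumption must stay at or above half the
    lactate production at every dose (one glucose yields at most two
    lactates).
    """

    doses: tuple[float, ...] = (0.0, 0.1, 0.5, 1.0, 5.0)  # ug/mL, vehicle first
    growth_rate_per_dose: tuple[float, ...] = (0.020, 0.019, 0.018, 0.016, 0.012)  # 1/h
    replicates: int = 3
    duration_h: float = 96.0
    seed_count: int = 50_000
    volume_ml: float = 2.0
    interval_range_h: tuple[float, float] = (20.0, 24.0)
    fresh_glucose_mM: float = 17.5
    fresh_lactate_mM: float = 0.0
    glucose_rate0: float = 200.0   # nmol/h per 1e6 cells
    glucose_slope: float = 25.0    # per ug/mL
    lactate_rate0: float = 300.0
    lactate_slope: float = 40.0
    ocr0: float = 6.0              # pmol/min/ug protein
    ocr_slope: float = -1.0
    protein_pg_per_cell: float = 200.0
    cv: float = 0.05               # multiplicative lognormal measurement CV
    growth_timepoints_h: tuple[float, ...] = (0.0, 24.0, 72.0, 96.0)

    def validate(self) -> None:
        if len(self.doses) < 2 or 0.0 not in self.doses:
            raise ValueError("need >= 2 doses including a zero-dose vehicle")
        if len(self.growth_rate_per_dose) != len(self.doses):
            raise ValueError("growth_rate_per_dose must align with doses")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.replicates < 1 or self.seed_count < 1:
            raise ValueError("replicates and seed_count must be >= 1")
        for d in self.doses:
            glc = self.glucose_rate0 + self.glucose_slope * d
            lac = self.lactate_rate0 + self.lactate_slope * d
            ocr = self.ocr0 + self.ocr_slope * d
            if lac < 0 or glc < 0 or ocr < 0:
                raise ValueError(f"negative expected rate at dose {d}")
            if glc < lac / 2.0:
                raise ValueError(
                    f"dose {d}: expected glucose consumption {glc} below the "
                    f"stoichiometric floor lactate/2 = {lac / 2.0}"
                )

    def expected_rates(self, dose: float) -> dict[str, float]:
        """Noise-free rates at one dose (the generator's mean structure)."""
        return {
            "glucose": self.glucose_rate0 + self.glucose_slope * dose,
            "lactate": self.lactate_rate0 + self.lactate_slope * dose,
            "ocr": self.ocr0 + self.ocr_slope * dose,
        }


@dataclass(frozen=True)
class SimulationConfig:
    """Study-level simulation parameters.

    Expression defaults emulate a two-condition log2 Affymetrix-style
    comparison: ~2.5 probesets per gene, 20% of genes paired as isozymes
    under a shared EC, additive Gaussian noise on log2 intensities, and
    three arrays per class (experimental triplicate).
    """

    seed: int = 0
    n_genes: int = 2000
    probes_per_gene: tuple[int, int] = (1, 4)
    isozyme_fraction: float = 0.2
    n_samples_per_class: int = 3
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    probe_offset_sd: float = 0.5
    noise_sd: float = 0.25
    n_pathways: int = 50
    pathway_size: int = 30
    planted_pathways: tuple[PlantedEffect, ...] = ()
    assay: AssayConfig = field(default_factory=AssayConfig)

    def validate(self) -> None:
        if not 0.0 <= self.isozyme_fraction <= 1.0:
            raise ValueError("isozyme_fraction must be in [0, 1]")
        if min(self.n_genes, self.n_samples_per_class, self.n_pathways, self.pathway_size) < 1:
            raise ValueError("all counts must be >= 1")
        if self.n_samples_per_class < 2:
            raise ValueError("need >= 2 samples per class")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        lo, hi = self.probes_per_gene
        if lo < 1 or hi < lo:
            raise ValueError("probes_per_gene must be a range with 1 <= lo <= hi")
        self.assay.validate()

    def with_planted(self, *effects: PlantedEffect) -> "SimulationConfig":
        return replace(self, planted_pathways=tuple(effects))


def _ec_id(k: int) -> str:
    # unique 4-field EC-style id for k < 3000
    return f"{k % 6 + 1}.{(k // 6) % 20 + 1}.{(k // 120) % 25 + 1}.{k // 3000 + 1}"


def simulate_expression(
    config: SimulationConfig,
) -> tuple[ExpressionStudy, EnzymeMap, PathwayCatalog, pd.DataFrame]:
    """Generate a two-class study with annotation, catalog and truth table.

    Genes in planted pathways have their treated-class mean shifted by
    ``delta * noise_sd`` in the planted direction, identically for every
    probeset of the gene.  The truth table (columns ``pathway``, ``delta``,
    ``direction``) lists every planted effect; under a null configuration
    it is empty.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ng = config.n_genes

    symbols = [f"GENE{i:05d}" for i in range(ng)]
    unigenes = [f"Hs.{100000 + i}" for i in range(ng)]

    # isozyme pairing: shared EC for consecutive shuffled gene pairs
    n_pairs = int(round(config.isozyme_fraction * ng / 2.0))
    order = rng.permutation(ng)
    gene_ec = np.empty(ng, dtype=object)
    ec_counter = 0
    for p in range(n_pairs):
        ec = _ec_id(ec_counter)
        ec_counter += 1
        gene_ec[order[2 * p]] = ec
        gene_ec[order[2 * p + 1]] = ec
    for g in order[2 * n_pairs:]:
        gene_ec[g] = _ec_id(ec_counter)
        ec_counter += 1
    all_ecs = sorted(set(gene_ec))

    # disjoint pathways over a shuffled EC pool
    needed = config.n_pathways * config.pathway_size
    if needed > len(all_ecs):
        raise ValueError(
            f"catalog needs {needed} ECs but only {len(all_ecs)} exist; "
            "reduce n_pathways/pathway_size or raise n_genes"
        )
    pool = list(rng.permutation(all_ecs))
    native = {
        f"PATHWAY_{i + 1:03d}": frozenset(pool[i * config.pathway_size:(i + 1) * config.pathway_size])
        for i in range(config.n_pathways)
    }
    catalog = build_catalog(native)

    planted_by_name = {}
    for eff in config.planted_pathways:
        if eff.pathway not in catalog.sets:
            raise ValueError(f"planted pathway {eff.pathway!r} is not in the generated catalog")
        if eff.pathway in planted_by_name:
            raise ValueError(f"pathway {eff.pathway!r} planted twice")
        planted_by_name[eff.pathway] = eff
    ec_shift: dict[str, float] = {}
    for name, eff in planted_by_name.items():
        for ec in catalog.sets[name]:
            ec_shift[ec] = eff.direction * eff.delta * config.noise_sd

    # probesets
    lo, hi = config.probes_per_gene
    probe_counts = rng.integers(lo, hi + 1, size=ng)
    probeset_ids: list[str] = []
    probe_gene: list[int] = []
    counter = 200000
    for g in range(ng):
        for _ in range(probe_counts[g]):
            probeset_ids.append(f"{counter}_at")
            counter += 1
            probe_gene.append(g)
    probe_gene_arr = np.asarray(probe_gene)
    n_probe = len(probeset_ids)

    ns = config.n_samples_per_class
    sample_ids = [f"DOX_{i + 1}" for i in range(ns)] + [f"VEH_{i + 1}" for i in range(ns)]
    labels = ["DOX"] * ns + ["VEH"] * ns

    gene_base = rng.normal(config.baseline_mean, config.baseline_sd, size=ng)
    probe_offset = rng.normal(0.0, config.probe_offset_sd, size=n_probe)
    gene_shift = np.array([ec_shift.get(gene_ec[g], 0.0) for g in range(ng)])
    mean = gene_base[probe_gene_arr, None] + probe_offset[:, None] + np.zeros((n_probe, 2 * ns))
    mean[:, :ns] += gene_shift[probe_gene_arr, None]
    values = mean + rng.normal(0.0, config.noise_sd, size=(n_probe, 2 * ns))

    study = ExpressionStudy(
        values=pd.DataFrame(values, index=pd.Index(probeset_ids, name="Name"), columns=sample_ids),
        labels=pd.Series(labels, index=sample_ids, name="class"),
        classes=("DOX", "VEH"),
    )
    emap = EnzymeMap(
        probeset_to_unigene={probeset_ids[i]: unigenes[probe_gene[i]] for i in range(n_probe)},
        unigene_to_symbol=dict(zip(unigenes, symbols)),
        symbol_to_ecs={symbols[g]: frozenset([gene_ec[g]]) for g in range(ng)},
    )
    truth = pd.DataFrame(
        [
            {"pathway": e.pathway, "delta": e.delta, "direction": e.direction}
            for e in config.planted_pathways
        ],
        columns=["pathway", "delta", "direction"],
    )
    return study, emap, catalog, truth


def simulate_assay_plate(config: SimulationConfig) -> AssayPlate:
    """Generate endpoint assay wells and a proliferation time course.

    Cell counts grow exponentially from a common seeding count at the
    dose's rate; metabolite concentration changes are consistent with the
    per-well realized rate and the endpoint cell count (so a zero-CV plate
    round-trips exactly through the rate calculations); measurement noise
    is multiplicative lognormal with the configured CV.  Concentrations
    that would fall below zero are clipped to zero, with the clip recorded
    in the plate metadata.
    """
    config.validate()
    a = config.assay
    rng = np.random.default_rng(config.seed + 1)  # distinct stream from expression
    sigma = math.sqrt(math.log(1.0 + a.cv ** 2)) if a.cv > 0 else 0.0

    def noisy(x: float) -> float:
        if sigma == 0.0:
            return x
        return x * rng.lognormal(-sigma * sigma / 2.0, sigma)

    clip_notes: list[str] = []
    rows = []
    growth_rows = []
    for di, dose in enumerate(a.doses):
        g = a.growth_rate_per_dose[di]
        exp_rates = a.expected_rates(dose)
        for rep in range(1, a.replicates + 1):
            interval = rng.uniform(*a.interval_range_h)
            count = int(round(noisy(a.seed_count * math.exp(g * a.duration_h))))
            # count when the fresh media went on, back-extrapolated at rate g
            count_start = int(round(count * math.exp(-g * interval)))
            glc_rate = noisy(exp_rates["glucose"])
            lac_rate = noisy(exp_rates["lactate"])
            ocr_rate = noisy(exp_rates["ocr"])
            cells_m = count / 1e6
            d_glc = glc_rate * cells_m * interval / (a.volume_ml * 1000.0)
            d_lac = lac_rate * cells_m * interval / (a.volume_ml * 1000.0)
            final_glc = a.fresh_glucose_mM - d_glc
            final_lac = a.fresh_lactate_mM + d_lac
            well = f"D{di}R{rep}"
            if final_glc < 0.0:
                clip_notes.append(f"{well}: final glucose {final_glc:.4g} mM clipped to 0")
                final_glc = 0.0
            if final_lac < 0.0:
                clip_notes.append(f"{well}: final lactate {final_lac:.4g} mM clipped to 0")
                final_lac = 0.0
            protein = count * a.protein_pg_per_cell / 1e6  # ug
            rows.append({
                "well": well, "drug": "Dox", "dose_ug_ml": dose, "replicate": rep,
                "fresh_glucose_mM": a.fresh_glucose_mM, "final_glucose_mM": final_glc,
                "fresh_lactate_mM": a.fresh_lactate_mM, "final_lactate_mM": final_lac,
                "volume_ml": a.volume_ml, "interval_h": interval, "cell_count": count,
                "cell_count_start": count_start,
                "o2_pmol_min": ocr_rate * protein, "protein_ug": protein,
            })
            for t in a.growth_timepoints_h:
                growth_rows.append({
                    "dose_ug_ml": dose, "replicate": rep, "timepoint_h": t,
                    "cell_count": int(round(noisy(a.seed_count * math.exp(g * t)))),
                })
    meta = {"n_clipped": len(clip_notes), "clip_notes": clip_notes}
    return AssayPlate(wells=pd.DataFrame(rows), growth=pd.DataFrame(growth_rows), meta=meta)
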