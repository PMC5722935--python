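"""Synthetic data generation.

Generates fully synthetic inputs with the statistical structure the
analysis stages assume - a peptic peptide pool with lognormal abundances,
chromatographic peak areas under multiplicative noise, permeate peaks from
a charge- and size-dependent transmission model, and a saturating pH-stat
titration curve - so the whole pipeline is testable end-to-end with
recoverable ground truth and no external data.

The permeate ground-truth transmission model is an invention of this
package for testing purposes (it is NOT an experimental separation model):
steric sieving modulated by a logistic attenuation in |net charge| at the
operating pH and an exponential penalty for strongly hydrophobic peptides,

    T = sieve(MW, MWCO) * 2 / (1 + exp(c * |z|)) * exp(-h * max(0, gravy - g0)),

chosen to encode, qualitatively, charge effects dominating over sieving
and hydrophobic retention on PES membranes.  Setting c = h = 0 reduces T
to the pure sieving coefficient.

All draws flow from one seeded generator per run; each stage consumes a
documented substream (spawn keys: 0 hydrolysate, 1 filtration - offset by
condition, 2 pH-stat) so changing one stage's noise never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np

from .digestion import TheoreticalPeptide, enumerate_peptides, find_cleavage_sites
from .masses import peptide_mass
from .peaks import PeakRecord, PeakTable
from .physchem import PkaTable, default_pka_table, gravy, net_charge
from .phstat import PhStatRecord
from .rules import load_rule_set
from .sequences import ProteinSequence, mature_bsa
from .transmission import PES1, PES5, MembraneSpec, tr_theoretical


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the synthetic experiment.

    Defaults mirror the emulated bench conditions: a 3 g/L serum-albumin
    peptic digest sampled every 15 min for 3 h on a pH-stat titrating
    0.1 N base, fractionated at pH 2 and pH 10 through 5 kDa and 1 kDa
    polyethersulfone membranes.
    """

    seed: int = 0
    substrate: ProteinSequence | None = None  # None -> bundled mature BSA
    enzyme: str = "pepsin-ph2"
    n_peptides: int = 60
    min_length: int = 3
    max_missed: int = 1
    # lognormal abundance model (log-space location/scale, arbitrary units)
    abundance_mu: float = 4.0
    abundance_sigma: float = 1.0
    # multiplicative lognormal noise on peak areas; additive mass jitter (Da)
    peak_noise_sigma: float = 0.2
    mass_jitter_sigma: float = 0.05
    # transmission ground-truth model
    membranes: tuple[MembraneSpec, ...] = (PES1, PES5)
    ph_values: tuple[float, ...] = (2.0, 10.0)
    charge_attenuation: float = 1.0
    gravy_penalty: float = 0.3
    gravy_threshold: float = 1.5
    # first-order pH-stat kinetics: A(t) = a_inf * (1 - exp(-k t)) + noise
    phstat_k: float = 0.03  # 1/min; plateau from ~2 h on
    phstat_a_inf_ml: float = 29.5  # ~65.5% relative DH at the study constants
    phstat_noise_sigma: float = 0.3  # mL, additive Gaussian
    phstat_t_max_min: float = 180.0
    phstat_dt_min: float = 15.0

    def __post_init__(self) -> None:
        if self.n_peptides < 1:
            raise ValueError("n_peptides must be >= 1")
        for name in ("abundance_sigma", "peak_noise_sigma", "mass_jitter_sigma",
                     "phstat_noise_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.phstat_k <= 0 or self.phstat_a_inf_ml <= 0:
            raise ValueError("phstat kinetics need k > 0 and a_inf > 0")

    def resolve_substrate(self) -> ProteinSequence:
        return self.substrate if self.substrate is not None else mature_bsa()


def _rng(config: SimulationConfig, *spawn_key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=spawn_key))


@dataclass(frozen=True)
class GroundTruthPeptide:
    peptide: TheoreticalPeptide
    true_mass: float  # [M+H]+ monoisotopic, Da
    abundance: float  # true feed-level abundance, area units
    #: (membrane name, pH) -> true transmission fraction in [0, 1]
    transmission: dict = field(default_factory=dict)


@dataclass(frozen=True)
class GroundTruth:
    """Everything needed to score the pipeline against the generator."""

    peptides: tuple[GroundTruthPeptide, ...]
    phstat_k: float | None = None
    phstat_a_inf_ml: float | None = None

    def by_sequence(self) -> dict:
        return {g.peptide.sequence: g for g in self.peptides}


def simulate_hydrolysate(config: SimulationConfig) -> tuple[PeakTable, GroundTruth]:
    """Digest the substrate and emit a noisy hydrolysate peak table.

    The peptide pool is a random subset (without replacement, distinct
    sequences) of the specific peptic digest; abundances are lognormal;
    each peak sits at the peptide's [M+H]+ mass plus Gaussian jitter with
    area = abundance times multiplicative lognormal noise.  Deterministic
    for a fixed seed.
    """
    rng = _rng(config, 0)
    substrate = config.resolve_substrate()
    cmap = find_cleavage_sites(substrate, load_rule_set(config.enzyme))
    if not cmap.sites:
        import warnings

        warnings.warn("substrate has no cleavage sites; emitting the whole chain as one peak")
        pool = enumerate_peptides(substrate, cmap, min_length=1, mode="specific",
                                  max_missed=0)
    else:
        pool = enumerate_peptides(
            substrate, cmap, min_length=config.min_length, mode="specific",
            max_missed=config.max_missed,
        )
    by_seq: dict[str, TheoreticalPeptide] = {}
    for p in pool:
        by_seq.setdefault(p.sequence, p)
    sequences = sorted(by_seq)
    n = min(config.n_peptides, len(sequences))
    chosen = rng.choice(len(sequences), size=n, replace=False)
    selected = [by_seq[sequences[i]] for i in sorted(chosen)]

    truth_peptides = []
    records = []
    for p in selected:
        true_mass = peptide_mass(p.sequence, charge_form="protonated")
        abundance = float(rng.lognormal(config.abundance_mu, config.abundance_sigma))
        area = abundance * float(rng.lognormal(0.0, config.peak_noise_sigma)) \
            if config.peak_noise_sigma > 0 else abundance
        observed_mass = true_mass + float(rng.normal(0.0, config.mass_jitter_sigma)) \
            if config.mass_jitter_sigma > 0 else true_mass
        truth_peptides.append(
            GroundTruthPeptide(peptide=p, true_mass=true_mass, abundance=abundance)
        )
        records.append(
            PeakRecord(mass=observed_mass, area=area, intensity=area, stream="hydrolysate")
        )
    table = PeakTable(records=tuple(records), stream="hydrolysate")
    truth = GroundTruth(
        peptides=tuple(truth_peptides),
        phstat_k=config.phstat_k,
        phstat_a_inf_ml=config.phstat_a_inf_ml,
    )
    return table, truth


def true_transmission(
    sequence: str,
    mass: float,
    membrane: MembraneSpec,
    ph: float,
    config: SimulationConfig,
    pka: PkaTable | None = None,
) -> float:
    """The generator's ground-truth transmission fraction in [0, 1]."""
    sieve = tr_theoretical(mass, membrane) / 100.0
    z = abs(net_charge(sequence, ph, pka or default_pka_table()))
    charge_factor = 2.0 / (1.0 + np.exp(config.charge_attenuation * z))
    excess = max(0.0, gravy(sequence) - config.gravy_threshold)
    hydrophobic_factor = float(np.exp(-config.gravy_penalty * excess))
    return float(sieve * charge_factor * hydrophobic_factor)


def simulate_filtration(
    feed: PeakTable,
    truth: GroundTruth,
    config: SimulationConfig,
    membrane: MembraneSpec,
    ph: float,
) -> tuple[PeakTable, GroundTruth]:
    """Pass the simulated feed through one membrane condition.

    Permeate area = feed area x true transmission x multiplicative noise;
    peptides with zero transmission (lambda >= 1) drop out of the permeate.
    Returns the permeate table and the ground truth updated with this
    condition's true transmissions.
    """
    if membrane.mwco <= 0:
        raise ValueError("membrane MWCO missing or invalid")
    if len(feed.records) != len(truth.peptides):
        raise ValueError("feed table and ground truth are out of register")
    cond_index = 0
    conditions = [(m.name, p) for m in config.membranes for p in config.ph_values]
    key = (membrane.name, ph)
    cond_index = conditions.index(key) if key in conditions else len(conditions)
    rng = _rng(config, 1, cond_index)

    records = []
    updated = []
    for peak, gt in zip(feed.records, truth.peptides):
        t = true_transmission(gt.peptide.sequence, gt.true_mass, membrane, ph, config)
        transmission = dict(gt.transmission)
        transmission[key] = t
        updated.append(replace(gt, transmission=transmission))
        area = peak.area * t
        if config.peak_noise_sigma > 0:
            area *= float(rng.lognormal(0.0, config.peak_noise_sigma))
        if area <= 0:
            continue
        mass = gt.true_mass
        if config.mass_jitter_sigma > 0:
            mass += float(rng.normal(0.0, config.mass_jitter_sigma))
        records.append(
            PeakRecord(
                mass=mass, area=area, intensity=area,
                stream="permeate", membrane=membrane.name, ph=ph,
            )
        )
    permeate = PeakTable(
        records=tuple(records), stream="permeate", membrane=membrane.name, ph=ph
    )
    return permeate, replace(truth, peptides=tuple(updated))


def simulate_phstat(config: SimulationConfig) -> tuple[list[PhStatRecord], GroundTruth]:
    """A saturating pH-stat titration series with additive Gaussian noise.

    A(t) = a_inf * (1 - exp(-k t)) + N(0, sigma), clamped non-negative,
    sampled on the configured grid (default 0-180 min every 15 min).
    """
    rng = _rng(config, 2)
    times = np.arange(0.0, config.phstat_t_max_min + 1e-9, config.phstat_dt_min)
    clean = config.phstat_a_inf_ml * (1.0 - np.exp(-config.phstat_k * times))
    noise = rng.normal(0.0, config.phstat_noise_sigma, size=times.shape) \
        if config.phstat_noise_sigma > 0 else np.zeros_like(times)
    volumes = np.clip(clean + noise, 0.0, None)
    series = [PhStatRecord(float(t), float(v)) for t, v in zip(times, volumes)]
    truth = GroundTruth(
        peptides=(), phstat_k=config.phstat_k, phstat_a_inf_ml=config.phstat_a_inf_ml
    )
    return series, truth
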