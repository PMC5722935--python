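"""End-to-end workflow orchestration.

Runs the full chain - digest, identify, profile, DH curve, filtration -
and writes seven TSV reports plus a machine-readable run log:

    sites.tsv                cleavable bonds (index, P1, P1')
    peptides.tsv             theoretical peptide pool
    identifications.tsv      per-mass match status and exclusion reasons
    table1_like.tsv          physicochemical annotation of accepted peptides
    dh_curve.tsv             time, DH, relative DH
    transmissions.tsv        per-peptide Tr_obs / Tr_theo per condition
    separation_factors.tsv   group-pair selectivity per condition
    run_log.json             parameters, seed, versions, exclusion counts

TSV is the canonical dialect (tab-separated, UTF-8, '.' decimal separator,
2-decimal presentation for annotation columns); the run log preserves full
precision for every scalar the reports round.  Reruns with an identical
configuration and seed produce byte-identical reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .digestion import enumerate_peptides, find_cleavage_sites
from .identification import match_masses, reconcile_streams
from .masses import pool_masses
from .peaks import filter_peaks, merge_peaks, read_peaks
from .physchem import annotate_peptide, group_summary, load_pka_table
from .phstat import DhParameters, build_curve, fit_first_order, read_phstat_csv
from .rules import load_rule_set
from .sequences import mature_bsa, read_fasta
from .simulate import SimulationConfig, simulate_filtration, simulate_hydrolysate, simulate_phstat
from .transmission import (
    MembraneSpec,
    TransmissionTable,
    build_transmission_records,
    condition_summary,
)

REPORTS = (
    "sites.tsv",
    "peptides.tsv",
    "identifications.tsv",
    "table1_like.tsv",
    "dh_curve.tsv",
    "transmissions.tsv",
    "separation_factors.tsv",
)


@dataclass(frozen=True)
class RunConfig:
    """Inputs, parameters and output location of one pipeline run.

    With no experimental inputs given, the synthetic-data generator stands
    in for them (seeded by *seed*).
    """

    output_dir: str | Path
    fasta: str | Path | None = None
    hydrolysate_peaks: str | Path | None = None
    #: (membrane name, pH) -> peak-list path
    permeate_peaks: dict = field(default_factory=dict)
    phstat_series: str | Path | None = None
    enzyme: str = "pepsin-ph2"
    tolerance: float = 0.3
    min_length: int = 3
    max_missed: int = 1
    pka_table: str = "table1-calibrated"
    membranes: tuple[MembraneSpec, ...] = (
        MembraneSpec("PES1", 1000.0),
        MembraneSpec("PES5", 5000.0),
    )
    ph_values: tuple[float, ...] = (2.0, 10.0)
    intensity_threshold: float = 0.10
    dh_params: DhParameters = field(default_factory=lambda: DhParameters(normality=0.1))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        for path in [self.fasta, self.hydrolysate_peaks, self.phstat_series,
                     *self.permeate_peaks.values()]:
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"input path does not exist: {path}")


def _write_tsv(df: pd.DataFrame, path: Path, round_cols: dict | None = None) -> None:
    out = df.copy()
    for col, nd in (round_cols or {}).items():
        if col in out.columns:
            out[col] = out[col].map(lambda v: f"{v:.{nd}f}" if pd.notna(v) else "")
    out.to_csv(path, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the run log as a dict.

    Any stage failure aborts with the stage name attached to the exception.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "pepflux_version": __version__,
        "seed": config.seed,
        "parameters": {
            "enzyme": config.enzyme,
            "tolerance_da": config.tolerance,
            "min_length": config.min_length,
            "max_missed": config.max_missed,
            "pka_table": config.pka_table,
            "intensity_threshold": config.intensity_threshold,
            "membranes": [[m.name, m.mwco] for m in config.membranes],
            "ph_values": list(config.ph_values),
            "dh_params": {
                "normality": config.dh_params.normality,
                "alpha": config.dh_params.alpha,
                "h_tot": config.dh_params.h_tot,
                "protein_mass_g": config.dh_params.protein_mass_g,
            },
        },
    }

    stage = "digest"
    try:
        substrate = (
            read_fasta(config.fasta) if config.fasta is not None else mature_bsa()
        )
        rule_set = load_rule_set(config.enzyme)
        cmap = find_cleavage_sites(substrate, rule_set)
        sites_df = pd.DataFrame(
            [
                {
                    "bond": b,
                    "p1": substrate.residue(b),
                    "p1_prime": substrate.residue(b + 1),
                }
                for b in sorted(cmap.sites)
            ]
        )
        _write_tsv(sites_df, outdir / "sites.tsv")
        pool = enumerate_peptides(
            substrate, cmap, min_length=config.min_length,
            mode="specific", max_missed=config.max_missed,
        )
        masses = pool_masses(pool, parent=substrate)
        peptides_df = pd.DataFrame(
            [
                {
                    "start": p.start, "end": p.end, "sequence": p.sequence,
                    "preceding": p.preceding, "following": p.following,
                    "missed_cleavages": p.missed_cleavages,
                    "mh_mono": m,
                }
                for p, m in zip(pool, masses)
            ]
        )
        _write_tsv(peptides_df, outdir / "peptides.tsv", round_cols={"mh_mono": 4})
        log["digest"] = {
            "substrate": substrate.identifier,
            "n_bonds": substrate.n_bonds,
            "n_sites": cmap.n_sites,
            "dh_max_percent": cmap.dh_max,
            "rule_set": rule_set.name,
            "n_pool_peptides": len(pool),
        }

        stage = "acquire"
        conditions = [(m, ph) for m in config.membranes for ph in config.ph_values]
        sim_cfg = SimulationConfig(
            seed=config.seed, substrate=substrate, enzyme=config.enzyme,
            membranes=config.membranes, ph_values=config.ph_values,
            min_length=config.min_length, max_missed=config.max_missed,
        )
        if config.hydrolysate_peaks is not None:
            feed = read_peaks(config.hydrolysate_peaks)
            permeates = {
                key: read_peaks(path) for key, path in config.permeate_peaks.items()
            }
            truth = None
        else:
            feed, truth = simulate_hydrolysate(sim_cfg)
            permeates = {}
            for membrane, ph in conditions:
                permeate, truth = simulate_filtration(feed, truth, sim_cfg, membrane, ph)
                permeates[(membrane.name, ph)] = permeate

        stage = "identify"
        feed = merge_peaks(filter_peaks(feed, config.intensity_threshold))
        feed_matches = match_masses(
            feed, pool, tolerance=config.tolerance,
            min_length=config.min_length, parent=substrate,
        )
        permeate_matches = {
            key: match_masses(
                merge_peaks(table), pool, tolerance=config.tolerance,
                min_length=config.min_length, parent=substrate,
            )
            for key, table in permeates.items()
        }
        all_permeate = [m for matches in permeate_matches.values() for m in matches]
        reconciled = reconcile_streams(feed_matches, all_permeate, mass_window=config.tolerance)
        id_rows = []
        for m in reconciled.accepted:
            best = m.best
            id_rows.append(
                {
                    "observed_mass": m.observed_mass, "status": m.status,
                    "sequence": best.peptide.sequence,
                    "flanked": best.peptide.flanked,
                    "error_da": best.error, "reason": "",
                }
            )
        for e in reconciled.exclusions:
            id_rows.append(
                {
                    "observed_mass": e.observed_mass, "status": "excluded",
                    "sequence": "", "flanked": "", "error_da": np.nan,
                    "reason": e.reason,
                }
            )
        ids_df = pd.DataFrame(id_rows).sort_values(
            ["status", "observed_mass"]).reset_index(drop=True)
        _write_tsv(ids_df, outdir / "identifications.tsv",
                   round_cols={"observed_mass": 4, "error_da": 4})
        log["identify"] = {
            "n_feed_peaks": len(feed),
            "n_accepted": len(reconciled.accepted),
            "exclusion_counts": reconciled.exclusion_counts,
        }

        stage = "profile"
        pka = load_pka_table(config.pka_table)
        annotated = []
        for m in reconciled.accepted:
            best = m.best
            annotated.append(
                annotate_peptide(
                    best.peptide.sequence,
                    preceding=best.peptide.preceding,
                    following=best.peptide.following,
                    pka=pka,
                )
            )
        table1_df = pd.DataFrame(
            [
                {
                    "mw": r.mass, "preceding": r.preceding, "sequence": r.sequence,
                    "following": r.following, "charge_ph2": r.charge_ph2,
                    "charge_ph10": r.charge_ph10, "group": r.group,
                    "pi": r.pi, "gravy": r.gravy,
                }
                for r in annotated
            ]
        )
        _write_tsv(
            table1_df, outdir / "table1_like.tsv",
            round_cols={"mw": 2, "charge_ph2": 2, "charge_ph10": 2, "pi": 2, "gravy": 2},
        )
        summary = group_summary(annotated)
        log["profile"] = {
            "pka_table": pka.name,
            "groups": summary.table.to_dict(orient="index"),
        }

        stage = "dh"
        if config.phstat_series is not None:
            series = read_phstat_csv(config.phstat_series)
        else:
            series, _ = simulate_phstat(sim_cfg)
        curve = build_curve(series, config.dh_params, dh_max=cmap.dh_max)
        _write_tsv(curve.frame, outdir / "dh_curve.tsv",
                   round_cols={"volume_ml": 4, "dh": 4, "relative_dh": 4})
        fit = fit_first_order(series) if len(series) >= 3 else None
        log["dh"] = {
            "dh_max_percent": cmap.dh_max,
            "final_dh_percent": float(curve.frame["dh"].iloc[-1]),
            "final_relative_dh_percent": float(curve.frame["relative_dh"].iloc[-1]),
            "plateau_time_min": curve.plateau_time_min,
            "fitted_k_per_min": fit.k if fit else None,
            "fitted_a_inf_ml": fit.a_inf_ml if fit else None,
        }

        stage = "filtration"
        feed_areas = {
            m.best.peptide.sequence: m.peak.area
            for m in reconciled.accepted if m.peak is not None
        }
        records = []
        membranes_by_name = {m.name: m for m in config.membranes}
        for key, table in permeates.items():
            membrane = membranes_by_name[key[0]]
            ph = key[1]
            permeate_areas: dict[str, float] = {}
            for m in reconciled.accepted:
                if m.peak is None:
                    continue
                area = sum(
                    r.area for r in table.records
                    if abs(r.mass - m.observed_mass) <= config.tolerance
                )
                permeate_areas[m.best.peptide.sequence] = area
            sub = build_transmission_records(
                annotated, feed_areas, permeate_areas, membrane, ph
            )
            records.extend(sub.records)
        tr_table = TransmissionTable(records=tuple(records))
        _write_tsv(tr_table.to_frame(), outdir / "transmissions.tsv",
                   round_cols={"tr_obs": 2, "tr_theo": 2})
        sf = tr_table.separation_factors()
        _write_tsv(sf, outdir / "separation_factors.tsv", round_cols={"s": 2})
        if len(tr_table):
            cond = condition_summary(tr_table)
            log["filtration"] = {
                "n_records": len(tr_table),
                "condition_summary": json.loads(cond.to_json(orient="records")),
                "cross_membrane_ratios": json.loads(
                    cond.attrs["cross_membrane_ratios"].to_json(orient="records")
                ),
            }
        else:
            log["filtration"] = {"n_records": 0}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    return log
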