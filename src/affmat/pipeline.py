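"""End-to-end orchestration: interface -> design -> mutants -> energetics
-> kinetics -> report, deterministic under a fixed config + seed.

Each stage is a thin call into the library modules; stages whose inputs
are unavailable are skipped cleanly and recorded in the report.  Every
table written to disk carries the configuration hash so outputs are
traceable to the exact run that produced them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .design import MutationSpec, ResiduePropertyTable, build_mutant, \
    propose_mutations, proposals_to_frame
from .energetics import additivity, delta_decomposition
from .forcefield import default_forcefield
from .kinetics import AffinityRow, affinity_rows_to_frame, fit_langmuir, \
    fold_increase, kd_from_rates
from .structures import ContactCriteria, Structure, classify_contacts, \
    contacts_to_frame, find_interface_residues, read_structure
from .synthetic import EnsembleSpec, make_benchmark_complex, make_ensemble, \
    make_sensorgram_set

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "validate_tables"]

#: Default kinetic inputs for the simulation+fit stage: wild type and the
#: two strongly improved double mutants (published rates).
DEFAULT_RATE_SETS: Dict[str, Tuple[float, float]] = {
    "Wild-type": (2.84e4, 2.22e-3),
    "M41E/F63W": (2.01e4, 5.23e-7),
    "V134L/H159Q": (4.41e4, 6.12e-6),
}


@dataclass
class PipelineConfig:
    """Inputs, chain assignment, cutoffs and stage switches for one run."""

    complex_pdb: Optional[str] = None      # path; None -> synthetic benchmark
    receptor_chains: Tuple[str, ...] = ("A",)
    target_chains: Tuple[str, ...] = ("B",)
    interface_cutoff: float = 6.0          # A
    contact_criteria: ContactCriteria = field(default_factory=ContactCriteria)
    max_per_site: int = 2
    build_mutants: Tuple[Tuple[str, int, str, str], ...] = ()  # (chain,pos,wt,new)
    run_energetics: bool = False
    energetics_pairs: Tuple[Tuple[str, str, str], ...] = ()    # (double, s1, s2)
    n_snapshots: int = 20
    positional_sd: float = 0.3             # A
    run_kinetics: bool = True
    rate_sets: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RATE_SETS))
    rmax: float = 100.0                    # RU
    noise_sd: float = 2.0                  # RU
    seed: int = 0
    output_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.interface_cutoff <= 0:
            raise ValueError("interface cutoff must be positive")
        if set(self.receptor_chains) & set(self.target_chains):
            raise ValueError("receptor and target chains must be disjoint")

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("output_dir", None)
        text = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:12]


@dataclass
class RunReport:
    """All tables produced by one pipeline run, plus provenance."""

    interface: Optional[pd.DataFrame] = None
    proposals: Optional[pd.DataFrame] = None
    energy: Optional[pd.DataFrame] = None
    additivity_table: Optional[pd.DataFrame] = None
    affinity: Optional[pd.DataFrame] = None
    warnings: List[str] = field(default_factory=list)
    stages: Dict[str, str] = field(default_factory=dict)
    provenance: Dict[str, str] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tables = {
            "interface.csv": self.interface,
            "proposals.csv": self.proposals,
            "energy_decomposition.csv": self.energy,
            "additivity.csv": self.additivity_table,
            "affinity.csv": self.affinity,
        }
        h = self.provenance.get("config_hash", "")
        for name, frame in tables.items():
            if frame is None:
                continue
            out = frame.copy()
            out["config_hash"] = h
            out.to_csv(outdir / name, index=False, float_format="%.6g")
        meta = {"stages": self.stages, "warnings": self.warnings,
                "provenance": self.provenance}
        (outdir / "run_report.json").write_text(json.dumps(meta, indent=2))


def _load_complex(cfg: PipelineConfig) -> Structure:
    if cfg.complex_pdb is None:
        return make_benchmark_complex()
    return read_structure(Path(cfg.complex_pdb).read_text(),
                          label=cfg.complex_pdb)


def _energetics_stage(cfg: PipelineConfig, structure: Structure,
                      report: RunReport) -> None:
    """Build mutants, perturbation ensembles, and the decomposition tables."""
    ff = default_forcefield()
    target_chain = cfg.target_chains[0]
    specs = {f"{wt}{pos}{new}": MutationSpec(
        chain=chain, position=pos, wt_res=wt, new_res=new,
        rationale="hydrophobic" if new in "WFLIY" else
        ("charge" if new in "EDKR" else "hbond"),
        partner=(target_chain, 0, "UNK"))
        for chain, pos, wt, new in cfg.build_mutants}

    rng = np.random.SeedSequence(cfg.seed)
    seeds = iter(int(s.generate_state(1)[0] % (2 ** 31)) for s in
                 rng.spawn(1 + len(specs) + len(cfg.energetics_pairs)))
    wt_ens = make_ensemble(EnsembleSpec(
        base=structure, n_snapshots=cfg.n_snapshots,
        positional_sd=cfg.positional_sd, seed=next(seeds)))

    decomps = {}
    rows = []
    mut_structs: Dict[str, Structure] = {}
    for name, spec in specs.items():
        mut_structs[name] = build_mutant(structure, spec)
        ens = make_ensemble(EnsembleSpec(
            base=mut_structs[name], n_snapshots=cfg.n_snapshots,
            positional_sd=cfg.positional_sd, seed=next(seeds)))
        d = delta_decomposition(ens, wt_ens, [(spec.chain, spec.position)],
                                target_chain, ff)
        decomps[name] = d
        rows.append({"mutant": name, "delta_coulomb": d.delta_coulomb,
                     "delta_lj": d.delta_lj, "delta_hb": d.delta_hb,
                     "n_snapshots": d.n_snapshots})

    add_rows = []
    for double_name, s1_name, s2_name in cfg.energetics_pairs:
        parts = double_name.split("/")
        sub_specs = [specs[p] for p in parts]
        double_struct = structure
        for sp in sub_specs:
            double_struct = build_mutant(double_struct, sp)
        ens = make_ensemble(EnsembleSpec(
            base=double_struct, n_snapshots=cfg.n_snapshots,
            positional_sd=cfg.positional_sd, seed=next(seeds)))
        sites = [(sp.chain, sp.position) for sp in sub_specs]
        d_double = delta_decomposition(ens, wt_ens, sites, target_chain, ff)
        rows.append({"mutant": double_name,
                     "delta_coulomb": d_double.delta_coulomb,
                     "delta_lj": d_double.delta_lj,
                     "delta_hb": d_double.delta_hb,
                     "n_snapshots": d_double.n_snapshots})
        extra = additivity(d_double, decomps[s1_name], decomps[s2_name])
        add_rows.append({"double": double_name, "single_1": s1_name,
                         "single_2": s2_name, **{f"super_{k}": v
                                                 for k, v in extra.items()}})

    report.energy = pd.DataFrame(rows)
    report.additivity_table = pd.DataFrame(add_rows)


def _kinetics_stage(cfg: PipelineConfig, report: RunReport) -> None:
    ss = np.random.SeedSequence(cfg.seed + 1)
    children = ss.spawn(len(cfg.rate_sets))
    rows = []
    for (name, (ka, kd)), child in zip(cfg.rate_sets.items(), children):
        curves = make_sensorgram_set(ka, kd, cfg.rmax,
                                     noise_sd=cfg.noise_sd,
                                     seed=int(child.generate_state(1)[0]
                                              % (2 ** 31)))
        fit = fit_langmuir(curves)
        rows.append(AffinityRow(mutant=name, ka=fit.ka, kd=fit.kd, KD=fit.KD))
    wt = next((r for r in rows if r.mutant.lower().startswith("wild")), None)
    for r in rows:
        if wt is not None:
            r.fold_increase = fold_increase(wt.KD, r.KD)
    report.affinity = affinity_rows_to_frame(rows)


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Execute the configured stages in order; failures mark the stage and
    skip dependents.  Identical config + seed gives identical outputs."""
    report = RunReport()
    report.provenance = {"config_hash": cfg.config_hash(),
                         "seed": str(cfg.seed), "version": __version__}

    structure = None
    try:
        structure = _load_complex(cfg)
        contacts = find_interface_residues(
            structure, cfg.receptor_chains, cfg.target_chains,
            cfg.interface_cutoff)
        contacts = classify_contacts(structure, contacts,
                                     cfg.contact_criteria)
        report.interface = contacts_to_frame(contacts)
        report.stages["interface"] = "ok"
        logger.info("interface: %d contacts", len(contacts))
    except Exception as exc:  # noqa: BLE001 - reported, not swallowed silently
        report.stages["interface"] = f"failed: {exc}"
        contacts = None

    if contacts is not None:
        try:
            proposals = propose_mutations(
                contacts, ResiduePropertyTable.default(), cfg.max_per_site)
            report.proposals = proposals_to_frame(proposals)
            report.stages["design"] = "ok"
            logger.info("design: %d proposals", len(proposals))
        except Exception as exc:
            report.stages["design"] = f"failed: {exc}"
    else:
        report.stages["design"] = "skipped: interface unavailable"

    if cfg.run_energetics and structure is not None and cfg.build_mutants:
        try:
            _energetics_stage(cfg, structure, report)
            report.stages["energetics"] = "ok"
        except Exception as exc:
            report.stages["energetics"] = f"failed: {exc}"
    else:
        report.stages["energetics"] = "skipped"

    if cfg.run_kinetics and cfg.rate_sets:
        try:
            _kinetics_stage(cfg, report)
            report.stages["kinetics"] = "ok"
        except Exception as exc:
            report.stages["kinetics"] = f"failed: {exc}"
    else:
        report.stages["kinetics"] = "skipped"

    if report.affinity is not None:
        report.warnings = validate_tables(report.affinity)

    if cfg.output_dir:
        report.write(cfg.output_dir)
    return report


def validate_tables(affinity: pd.DataFrame,
                    kd_tolerance: float = 0.05,
                    fold_tolerance: float = 0.10) -> List[str]:
    """Internal-consistency checks on an affinity table.

    Flags rows where the printed/stored K_D deviates from kd/ka by more
    than ``kd_tolerance`` (relative), and rows whose fold-increase is
    inconsistent with the wild-type/mutant K_D ratio beyond
    ``fold_tolerance`` (which absorbs printed rounding).
    """
    if affinity is None or affinity.empty:
        return []

    def col(*names):
        for n in names:
            if n in affinity.columns:
                return n
        return None

    c_mut = col("mutant")
    c_ka = col("ka", "ka_per_M_s")
    c_kd = col("kd", "kd_per_s")
    c_KD = col("KD", "KD_M")
    c_fold = col("fold_increase", "fold")
    warnings_out: List[str] = []
    if not (c_mut and c_ka and c_kd and c_KD):
        return warnings_out

    wt_kd = None
    for r in affinity.itertuples():
        name = str(getattr(r, c_mut))
        if name.strip().lower() in ("wild-type", "wildtype", "wt",
                                    "wild type"):
            wt_kd = float(getattr(r, c_KD))
    for r in affinity.itertuples():
        name = str(getattr(r, c_mut))
        ka, kd = float(getattr(r, c_ka)), float(getattr(r, c_kd))
        KD = float(getattr(r, c_KD))
        ratio = kd_from_rates(ka, kd)
        if abs(ratio - KD) / KD > kd_tolerance:
            warnings_out.append(
                f"{name}: kd/ka = {ratio:.3g} M deviates from stored "
                f"K_D = {KD:.3g} M by {abs(ratio - KD) / KD:.1%}")
        if c_fold and wt_kd is not None:
            fold = getattr(r, c_fold)
            if fold is not None and np.isfinite(fold) and fold > 0:
                expected = wt_kd / KD
                if abs(fold - expected) / expected > fold_tolerance:
                    warnings_out.append(
                        f"{name}: fold-increase {fold:.3g} inconsistent "
                        f"with K_D ratio {expected:.3g}")
    return warnings_out
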