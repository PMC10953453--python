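"""End-to-end orchestration: deconvolve MS1, assign MS2, profile, report.

Each stage is a library call writing a flat TSV; the report is a
human-readable flat-text summary (masses, disulfide inference, coverage,
top bond-pair cells, per-domain fractions, sequence tags). Re-running on
identical inputs produces byte-identical tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .chem import (
    MassMode,
    Proteoform,
    chain_mass,
    infer_disulfide_count,
    proteoform_mass,
    read_fasta,
)
from .errors import MemtopError
from .fragments import generate_by_ions, infeasible_sites, write_theory_tsv
from .matching import match_peaks, group_repeats, write_assignments_tsv
from .ms1 import detect_adducts, detect_series, series_mass
from .peaks import PeakList, read_mgf, read_peaklist_tsv
from .sitestats import (
    fragment_summary,
    pair_heatmap,
    sequence_coverage,
    site_profile,
    write_pair_matrix_tsv,
    write_site_profile_tsv,
)
from .topology import Topology, domain_summary, read_topology, sequence_tags

log = logging.getLogger("memtop")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Inputs, tolerances and options for one pipeline run."""

    fasta: str | None = None
    topology: str | None = None
    ms1: str | None = None
    ms2: str | None = None
    out_dir: str = "memtop_out"
    disulfides: list[tuple[int, int]] = field(default_factory=list)
    n_copies: int = 1
    mass_mode: str = "average"
    mz_tol: float = 0.5
    tol_ppm: float = 10.0
    z_min: int = 5
    z_max: int = 30
    fragment_z_max: int = 10
    min_members: int = 3
    norm: str = "charge"
    adduct_window: tuple[float, float] = (700.0, 730.0)
    adduct_max_steps: int = 10
    min_tag_len: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.mz_tol <= 0 or self.tol_ppm <= 0:
            raise MemtopError("tolerances must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "disulfides" in raw:
            raw["disulfides"] = [tuple(p) for p in raw["disulfides"]]
        if "adduct_window" in raw:
            raw["adduct_window"] = tuple(raw["adduct_window"])
        return cls(**raw)


@dataclass
class PipelineResult:
    proteoform: Proteoform | None
    mass_estimates: list[tuple[float, float]]
    disulfide_inference: tuple[int, float] | None
    coverage: float | None
    report_path: Path


def _load_ms2(path: str, z: int | None) -> PeakList:
    if str(path).lower().endswith(".mgf"):
        return read_mgf(path)[0]
    return read_peaklist_tsv(path, ms_level=2, precursor_z=z)


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run every applicable stage and write the report bundle."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mode = MassMode.AVERAGE if cfg.mass_mode.startswith("av") else MassMode.MONOISOTOPIC
    lines: list[str] = ["# memtop pipeline report", ""]

    proteoform = None
    topo: Topology | None = None
    if cfg.fasta:
        proteoform = read_fasta(cfg.fasta, n_copies=cfg.n_copies)[0]
        if cfg.disulfides:
            proteoform = Proteoform(
                proteoform.name,
                proteoform.sequence,
                n_copies=proteoform.n_copies,
                disulfides=list(cfg.disulfides),
            )
        m = proteoform_mass(proteoform, mode)
        lines.append(
            f"proteoform: {proteoform.name} (L={proteoform.length}, "
            f"n_copies={proteoform.n_copies}, "
            f"disulfides={len(proteoform.disulfides)})"
        )
        lines.append(f"theoretical_mass_{mode.value}: {m:.2f} Da")
    if cfg.topology:
        try:
            topo = read_topology(cfg.topology)
        except MemtopError as exc:
            raise MemtopError(f"stage topology: {exc}") from exc

    mass_estimates: list[tuple[float, float]] = []
    disulfide_inf = None
    if cfg.ms1:
        try:
            pl1 = read_peaklist_tsv(cfg.ms1, ms_level=1)
            series = detect_series(
                pl1, cfg.z_min, cfg.z_max, cfg.mz_tol, cfg.min_members
            )
            lines.append("")
            lines.append(f"ms1_series_detected: {len(series)}")
            decon_rows = []
            for rank, s in enumerate(series):
                m, sd = series_mass(s, pl1)
                mass_estimates.append((m, sd))
                lines.append(
                    f"series_{rank}: mass {m:.1f} +/- {sd:.1f} Da, "
                    f"charges {min(s.charges)}..{max(s.charges)}, "
                    f"summed_intensity {s.total_intensity:.1f}"
                )
                for i, z in s.members:
                    decon_rows.append((float(pl1.mz[i]), float(pl1.intensity[i]), z, rank))
            import pandas as pd

            pd.DataFrame(
                decon_rows, columns=["mz", "intensity", "z", "series_id"]
            ).to_csv(out / "ms1_series.tsv", sep="\t", index=False,
                     float_format="%.6f")
            if mass_estimates and proteoform is not None:
                chain = proteoform_mass(
                    Proteoform(proteoform.name, proteoform.sequence,
                               n_copies=proteoform.n_copies),
                    MassMode.AVERAGE,
                )
                n_ss, resid = infer_disulfide_count(mass_estimates[0][0], chain)
                disulfide_inf = (n_ss, resid)
                lines.append(
                    f"disulfide_inference: {n_ss} bridges "
                    f"(residual {resid:.2f} Da vs chain mass {chain:.1f})"
                )
            if len(mass_estimates) >= 1:
                masses = [(m, 1.0) for m, _ in mass_estimates]
                try:
                    ladder = detect_adducts(
                        masses, mass_estimates[0][0],
                        cfg.adduct_window, cfg.adduct_max_steps,
                    )
                    lines.append(
                        f"adduct_ladder: {ladder.n_steps} steps of "
                        f"{ladder.step_mass:.1f} Da"
                    )
                except MemtopError:
                    pass
        except MemtopError as exc:
            raise MemtopError(f"stage deconv ({cfg.ms1}): {exc}") from exc
    else:
        lines.append("")
        lines.append("ms1: absent, deconvolution skipped")

    coverage = None
    if cfg.ms2 and proteoform is not None:
        try:
            pl2 = _load_ms2(cfg.ms2, None)
            theory = generate_by_ions(proteoform, MassMode.MONOISOTOPIC)
            write_theory_tsv(theory, out / "theory.tsv")
            assignments = match_peaks(
                theory, pl2, tol_ppm=cfg.tol_ppm, z_max=cfg.fragment_z_max
            )
            write_assignments_tsv(assignments, out / "assignments.tsv")
            profile = site_profile(assignments, proteoform.length, norm=cfg.norm)
            write_site_profile_tsv(profile, out / "site_profile.tsv")
            coverage = sequence_coverage(assignments, proteoform.length)
            heat = pair_heatmap(assignments, proteoform.sequence, norm=cfg.norm)
            write_pair_matrix_tsv(heat, out / "pair_matrix.tsv")
            summ = fragment_summary(assignments)
            groups = group_repeats(assignments)
            lines.append("")
            lines.append(f"ms2_assignments: {len(assignments)}")
            lines.append(f"sequence_coverage_pct: {coverage:.1f}")
            lines.append(
                f"fragment_summary: mean_mass {summ.mean_mass:.1f} Da, "
                f"mean_charge {summ.mean_charge:.2f}, n_unique {summ.n_unique}"
            )
            if groups:
                g = groups[0]
                lines.append(
                    f"top_repeat_fragment: {g.ion_type}{g.site} at "
                    f"{g.n_charge_states} charge states"
                )
            flat = heat.stack().sort_values(ascending=False)
            top_cells = [
                f"{x}|{y}={v:.0f}" for (x, y), v in flat.head(3).items() if v > 0
            ]
            lines.append("top_pair_cells: " + ", ".join(top_cells))
            if topo is not None:
                masked = infeasible_sites(proteoform)
                summary = domain_summary(profile, topo, masked_sites=masked)
                summary.to_csv(out / "domain_summary.tsv", sep="\t",
                               index=False, float_format="%.6f")
                tags = sequence_tags(profile, topo, min_len=cfg.min_tag_len)
                lines.append("")
                for r in summary.itertuples(index=False):
                    lines.append(
                        f"domain {r.label} ({r.kind}): fraction "
                        f"{r.fraction_of_total:.3f}, longest_tag {r.longest_tag}, "
                        f"masked_sites {r.n_masked_sites}"
                    )
                lines.append(
                    "sequence_tags: "
                    + "; ".join(f"{lbl}:{a}-{b}" for lbl, a, b in tags)
                )
        except MemtopError as exc:
            (out / "FAILED").write_text(f"stage assign: {exc}\n")
            raise MemtopError(f"stage assign ({cfg.ms2}): {exc}") from exc
    elif cfg.ms2:
        lines.append("")
        lines.append("ms2 given without a sequence; assignment skipped")

    report = out / "report.txt"
    report.write_text("\n".join(lines) + "\n")
    log.info("report written to %s", report)
    return PipelineResult(proteoform, mass_estimates, disulfide_inf, coverage, report)
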