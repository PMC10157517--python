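"""End-to-end orchestration from a single YAML config.

Stages per cell type: spike-in rate estimation, replicate merging,
optional strand merging, depth filtering, classification per generation,
stable-site intersection with the fidelity summary, then across cell
types marker discovery, and (when annotations are provided) CGI-border
enrichment, nucleosome occupancy and feature-distribution profiles.
A manifest records parameters, input checksums and per-stage site counts,
and the emitted fidelity table is re-derived from the written
classification TSVs as an internal consistency check before the run is
declared successful.  Identical config + inputs give identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from . import io as mio
from .classify import (STABLE_CLASSES, classify_sites, filter_by_depth,
                       merge_replicates, merge_strands)
from .context import (border_enrichment_profile, feature_distribution,
                      nucleosome_occupancy_profile)
from .fidelity import fidelity_summary, stable_intersection
from .markers import find_markers
from .spikein import estimate_conversion_rates

log = logging.getLogger("methfidelity")


@dataclass
class ClassificationParams:
    min_depth: int = 100
    mode: str = "statistical"
    alpha: float = 0.05
    half_tol: float = 0.05
    merge_strands: bool = False
    error_floor: float = 1e-6

    def validate(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.mode not in ("statistical", "strict"):
            raise ValueError(f"unknown classification mode {self.mode!r}")


@dataclass
class ProfileParams:
    window: int = 1500
    bin_width: int = 50

    def validate(self) -> None:
        if self.window % self.bin_width != 0:
            raise ValueError("window must be a multiple of bin_width")


@dataclass
class PipelineConfig:
    output_dir: Path
    cell_types: dict                      # label -> {generation -> sample spec}
    classification: ClassificationParams = field(default_factory=ClassificationParams)
    profile: ProfileParams = field(default_factory=ProfileParams)
    cgi: Path | None = None
    features: dict = field(default_factory=dict)   # label -> path
    fragments: Path | None = None
    seed: int = 0

    def input_files(self) -> list[Path]:
        files: list[Path] = []
        for per_gen in self.cell_types.values():
            for spec in per_gen.values():
                files += [Path(p) for p in spec["replicates"]]
                files += [Path(spec["spike_unmeth"]), Path(spec["spike_meth"])]
        files += [Path(p) for p in self.features.values()]
        if self.cgi:
            files.append(Path(self.cgi))
        if self.fragments:
            files.append(Path(self.fragments))
        return files


def load_pipeline_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    ann = raw.get("annotations", {}) or {}
    cfg = PipelineConfig(
        output_dir=Path(raw["output_dir"]),
        cell_types={
            str(t): {int(g): spec for g, spec in gens["generations"].items()}
            for t, gens in raw["cell_types"].items()},
        classification=ClassificationParams(**raw.get("classification", {})),
        profile=ProfileParams(**raw.get("profile", {})),
        cgi=Path(ann["cgi"]) if ann.get("cgi") else None,
        features={k: Path(v) for k, v in (ann.get("features") or {}).items()},
        fragments=Path(ann["fragments"]) if ann.get("fragments") else None,
        seed=int(raw.get("seed", 0)),
    )
    cfg.classification.validate()
    cfg.profile.validate()
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage; returns the output directory (exit contract: raises
    on any failure, so callers can map success to exit code 0)."""
    missing = [str(p) for p in config.input_files() if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(
            "missing input file(s): " + ", ".join(sorted(set(missing))))
    cp = config.classification
    cp.validate()
    config.profile.validate()

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "classification": vars(cp).copy(),
            "profile": vars(config.profile).copy(),
        },
        "inputs": {str(p): _sha256(Path(p)) for p in config.input_files()},
        "stages": {},
    }

    classified: dict[tuple[str, int], pd.DataFrame] = {}
    stable_by_type: dict[str, dict[str, pd.DataFrame]] = {}
    rate_rows = []
    for cell_type, per_gen in config.cell_types.items():
        tdir = out / cell_type
        tdir.mkdir(exist_ok=True)
        for gen, spec in sorted(per_gen.items()):
            reps = [mio.read_methylation_calls(p) for p in spec["replicates"]]
            rates = estimate_conversion_rates(
                mio.read_methylation_calls(spec["spike_unmeth"]),
                mio.read_methylation_calls(spec["spike_meth"]))
            rate_rows.append({
                "cell_type": cell_type, "generation": gen,
                "conversion_rate": rates.conversion_rate,
                "inappropriate_conversion_rate": rates.inappropriate_conversion_rate,
                "n_unmeth_spike_obs": rates.n_unmeth_spike_obs,
                "n_meth_spike_obs": rates.n_meth_spike_obs,
            })
            merged = merge_replicates(reps)
            if cp.merge_strands:
                merged = merge_strands(merged)
            passing = filter_by_depth(merged, cp.min_depth)
            cls = classify_sites(passing, rates=rates, mode=cp.mode,
                                 alpha=cp.alpha, half_tol=cp.half_tol,
                                 error_floor=cp.error_floor)
            cls["cell_type"] = cell_type
            cls["generation"] = gen
            mio.write_site_table(cls, tdir / f"classified_g{gen}.tsv")
            classified[(cell_type, gen)] = cls
            manifest["stages"][f"{cell_type}/g{gen}"] = {
                "n_read": int(sum(len(r) for r in reps)),
                "n_merged": len(merged),
                "n_depth_passing": len(passing),
                "per_class": {c: int((cls["meth_class"] == c).sum())
                              for c in (*STABLE_CLASSES, "DYNAMIC")},
            }
            log.info("%s g%d: %d merged, %d pass depth", cell_type, gen,
                     len(merged), len(passing))

        g20, g30 = sorted(per_gen)
        stable_sets, table = stable_intersection(
            classified[(cell_type, g20)], classified[(cell_type, g30)])
        summary = fidelity_summary(table)
        summary.to_csv(tdir / "fidelity_table.tsv", sep="\t", index=False,
                       float_format="%.10g")
        for cls_name, sites in stable_sets.items():
            mio.write_sites_bed(sites, tdir / f"stable_{cls_name.lower()}.bed",
                                name_col="meth_class")
        stable_by_type[cell_type] = stable_sets

    pd.DataFrame(rate_rows).to_csv(out / "conversion_rates.tsv", sep="\t",
                                   index=False, float_format="%.10g")

    if len(config.cell_types) >= 2:
        markers = find_markers({
            t: {"FULL": s["FULL"], "NONE": s["NONE"]}
            for t, s in stable_by_type.items()})
        with open(out / "markers.tsv", "w") as fh:
            fh.write("#" + "\t".join(markers.columns) + "\n")
            markers.to_csv(fh, sep="\t", header=False, index=False)
        for t in config.cell_types:
            mio.write_sites_bed(markers[markers["marker_for"] == t],
                                out / f"markers_{t}.bed")
        manifest["stages"]["markers"] = {
            t: int((markers["marker_for"] == t).sum()) for t in config.cell_types}

    if config.cgi is not None:
        cgis = mio.read_intervals(config.cgi)
        for cell_type in config.cell_types:
            fg = stable_by_type[cell_type]["FULL"]
            g20 = sorted(config.cell_types[cell_type])[0]
            bg = classified[(cell_type, g20)]
            if len(fg):
                profile = border_enrichment_profile(
                    fg, bg, cgis, window=config.profile.window,
                    bin_width=config.profile.bin_width)
                profile.write(out / cell_type / "border_enrichment.tsv")
        if config.fragments is not None:
            frags = mio.read_fragments(config.fragments)
            occ = nucleosome_occupancy_profile(
                frags, cgis, window=config.profile.window,
                bin_width=config.profile.bin_width)
            occ.write(out / "nucleosome_occupancy.tsv")

    if config.features:
        feats = {label: mio.read_intervals(p)
                 for label, p in config.features.items()}
        for cell_type in config.cell_types:
            fg = stable_by_type[cell_type]["FULL"]
            if len(fg):
                dist = feature_distribution(fg, feats)
                dist.to_csv(out / cell_type / "feature_distribution.tsv",
                            sep="\t", index=False, float_format="%.10g")

    _consistency_check(config, out)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


def analyze_simulated(dataset, classification: ClassificationParams | None = None
                      ) -> dict[str, Any]:
    """Run the in-memory analysis chain on a simulated dataset.

    Per cell type: estimate spike-in rates per generation, merge
    replicates, depth-filter, classify, intersect generations; across cell
    types: discover markers.  Returns a dict with ``classified`` keyed by
    (cell_type, generation), ``stable`` keyed by cell type, ``tables``
    (fidelity summaries) keyed by cell type, ``rates`` keyed by
    (cell_type, generation) and ``markers``.
    """
    cp = classification or ClassificationParams()
    cp.validate()
    cfg = dataset.config
    classified: dict = {}
    stable: dict = {}
    tables: dict = {}
    rates: dict = {}
    for cell_type in cfg.cell_types:
        for gen in cfg.generations:
            unmeth, meth = dataset.spikes[(cell_type, gen)]
            r = estimate_conversion_rates(unmeth, meth)
            rates[(cell_type, gen)] = r
            merged = dataset.merged_calls(cell_type, gen)
            if cp.merge_strands:
                merged = merge_strands(merged)
            classified[(cell_type, gen)] = classify_sites(
                merged, rates=r if cp.mode == "statistical" else None,
                mode=cp.mode, alpha=cp.alpha, half_tol=cp.half_tol,
                min_depth=cp.min_depth, error_floor=cp.error_floor)
        g20, g30 = cfg.generations
        stable[cell_type], table = stable_intersection(
            classified[(cell_type, g20)], classified[(cell_type, g30)])
        tables[cell_type] = fidelity_summary(table)
    markers = None
    if len(cfg.cell_types) >= 2:
        markers = find_markers({
            t: {"FULL": stable[t]["FULL"], "NONE": stable[t]["NONE"]}
            for t in cfg.cell_types})
    return {"classified": classified, "stable": stable, "tables": tables,
            "rates": rates, "markers": markers}


def _consistency_check(config: PipelineConfig, out: Path) -> None:
    """Every fidelity-table number must be re-derivable from the emitted
    classification TSVs."""
    for cell_type, per_gen in config.cell_types.items():
        g20, g30 = sorted(per_gen)
        c20 = mio.read_site_table(out / cell_type / f"classified_g{g20}.tsv")
        c30 = mio.read_site_table(out / cell_type / f"classified_g{g30}.tsv")
        _, table = stable_intersection(c20, c30)
        written = pd.read_csv(out / cell_type / "fidelity_table.tsv", sep="\t")
        for cls in STABLE_CLASSES:
            w = written[written["meth_class"] == cls].iloc[0]
            r = table[table["meth_class"] == cls].iloc[0]
            for col in ("n_g20", "n_g30", "n_stable"):
                if int(w[col]) != int(r[col]):
                    raise RuntimeError(
                        f"consistency check failed for {cell_type}/{cls}/{col}: "
                        f"table {w[col]} vs re-derived {r[col]}")
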