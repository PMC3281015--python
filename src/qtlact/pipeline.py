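"""End-to-end orchestration: simulate -> map -> classify -> patterns ->
conservation -> candidates/networks, driven by one YAML config.

Every stage draws its randomness from a per-stage seed derived from the
single global seed by a fixed counter scheme, so a rerun with the same
config reproduces byte-identical outputs and individual stages can be
re-run in isolation.  A run manifest records the config snapshot, the
stage seeds, SHA-256 digests of all outputs, and stage timings.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import io as qio
from .classify import classify_hits, filter_probe_snp_cis
from .conservation import (
    eqtl_feature_table,
    sliding_conservation_ratio,
    track_correlation,
)
from .mapping import genomewide_pvalue, permutation_fdr, scan_all_traits
from .model import ConditionedTraitSet, GenotypeMatrix, QTLHit, RegionSpec
from .network import build_pattern_network, select_candidates, write_network
from .patterns import (
    cross_population_conservation,
    lrs_across_conditions,
    make_activity_pattern,
    summarize_patterns,
)
from .simulate import (
    MOUSE_CHROM_LENGTHS_MB,
    SimulationConfig,
    Study,
    make_two_panel_study,
    step_sharing,
)

log = logging.getLogger(__name__)

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "simulation": {
        "panels": ["LXS", "BXD"],
        "n_strains": [31, 30],
        "n_markers": [400, 500],
        "n_expression_traits": 80,
        "n_cis": 16,
        "n_syntenic_trans": 6,
        "n_nonsyntenic_trans": 18,
        "n_snps": 4000,
        "breakpoint_rate": 0.02,
        "sigma": 1.0,
        "effect_sizes": [2.0, 3.0],
        "unequal_groups": False,
        "sharing_patches": [["3", 110, 160], ["4", 120, 157], ["12", 0, 40]],
        "sharing_inside": 0.9,
        "sharing_outside": 0.15,
    },
    "mapping": {
        "n_perm": 200,
        "fdr_target": 0.05,
        "thresholds": None,  # e.g. {"LXS": 24, "BXD": 26} to fix them
        "shared_permutation": True,
    },
    "classification": {
        "cis_window_mb": 5.0,
        "probe_snp_filter": {},  # panel -> bool; needs probe_flags file
        "probe_flags_file": None,
    },
    "patterns": {"mode": "nearest"},
    "conservation": {"window_mb": 50.0, "step_mb": 5.0},
    "network": {"prefilter_lrs": 20.0, "include_r": 0.7, "edge_r": 0.8},
    "regions": [
        {
            "chromosome": "3", "start_mb": 126, "end_mb": 142,
            "focal_panel": "LXS", "phenotype": "ACTCNT", "focal_condition": "EC",
        },
        {
            "chromosome": "14", "start_mb": 0, "end_mb": 24,
            "focal_panel": "LXS", "phenotype": "OPEN", "focal_condition": "EC",
        },
        {
            "chromosome": "1", "start_mb": 22, "end_mb": 32,
            "focal_panel": "BXD", "phenotype": "ACTCNT", "focal_condition": "EC",
        },
    ],
}


def load_config(path: str | Path | None) -> dict[str, Any]:
    """Merge a YAML config file over the defaults (shallow per section)."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is None:
        return cfg
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    for key, value in user.items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def stage_seed(master_seed: int, stage_index: int) -> int:
    """Per-stage seed from the global seed and a fixed stage counter."""
    ss = np.random.SeedSequence([int(master_seed), int(stage_index)])
    return int(ss.generate_state(1)[0] % (2**31))


STAGE_INDEX = {
    "simulate": 0,
    "fdr": 1,
    "scan": 2,
    "patterns": 3,
    "conservation": 4,
    "behavior": 5,
    "candidates": 6,
}


def simulation_config_from_dict(sim: Mapping[str, Any], seed: int) -> SimulationConfig:
    sim = dict(sim)
    patches = sim.pop("sharing_patches", None)
    inside = sim.pop("sharing_inside", 0.9)
    outside = sim.pop("sharing_outside", 0.15)
    kwargs: dict[str, Any] = {"seed": seed}
    if patches is not None:
        kwargs["sharing"] = step_sharing(
            [(str(c), float(a), float(b)) for c, a, b in patches],
            inside=float(inside),
            outside=float(outside),
        )
    for key in (
        "panels", "n_strains", "n_markers", "effect_sizes", "conditions",
    ):
        if key in sim:
            kwargs[key] = tuple(sim.pop(key))
    if "chrom_lengths" in sim:
        kwargs["chrom_lengths"] = {
            str(k): float(v) for k, v in sim.pop("chrom_lengths").items()
        }
    kwargs.update(sim)
    return SimulationConfig(**kwargs)


def sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _hash_config(cfg: Mapping[str, Any]) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()


class PipelineRun:
    """Stateful pipeline over one output directory."""

    def __init__(self, config: dict[str, Any], out_dir: str | Path):
        self.config = config
        self.out_dir = Path(out_dir)
        self.out_dir.mkdir(parents=True, exist_ok=True)
        self.manifest: dict[str, Any] = {
            "config": copy.deepcopy(config),
            "config_digest": _hash_config(config),
            "stage_seeds": {},
            "outputs": {},
            "timings_s": {},
            "thresholds": {},
        }
        self.study: Study | None = None
        self.thresholds: dict[str, float] = {}
        self.hits: dict[tuple[str, str], list[QTLHit]] = {}
        self.patterns_by_panel: dict[str, list] = {}
        self.cross_by_panel: dict[str, list] = {}

    # -- helpers -----------------------------------------------------------
    def _record(self, stage: str, paths: list[Path], t0: float) -> None:
        self.manifest["timings_s"][stage] = round(time.perf_counter() - t0, 3)
        for p in paths:
            self.manifest["outputs"][str(p.relative_to(self.out_dir))] = sha256_file(p)

    def _seed(self, stage: str) -> int:
        s = stage_seed(self.config["seed"], STAGE_INDEX[stage])
        self.manifest["stage_seeds"][stage] = s
        return s

    @property
    def panels(self) -> list[str]:
        return list(self.config["simulation"]["panels"])

    def panel_data(self) -> dict[str, tuple[GenotypeMatrix, ConditionedTraitSet]]:
        assert self.study is not None
        return {
            p: (self.study.genotypes[p], self.study.traits[p]) for p in self.panels
        }

    # -- stages ------------------------------------------------------------
    def stage_simulate(self) -> None:
        t0 = time.perf_counter()
        seed = self._seed("simulate")
        sim_cfg = simulation_config_from_dict(self.config["simulation"], seed)
        self.study = make_two_panel_study(sim_cfg)
        paths = []
        gdir = self.out_dir / "genotypes"
        tdir = self.out_dir / "traits"
        gdir.mkdir(exist_ok=True)
        tdir.mkdir(exist_ok=True)
        for panel in self.panels:
            p = gdir / f"{panel}.geno"
            qio.write_geno(self.study.genotypes[panel], p)
            paths.append(p)
            ts = self.study.traits[panel]
            for cond in ts.conditions:
                q = tdir / f"{panel}_{cond}.csv"
                qio.write_trait_table(ts.values[cond], q)
                paths.append(q)
            a = tdir / f"{panel}_annotations.csv"
            ts.annotations.to_csv(a)
            paths.append(a)
        p = self.out_dir / "snps.csv"
        self.study.snps.table.to_csv(p, index=False, float_format="%.6f")
        paths.append(p)
        p = self.out_dir / "truth.tsv"
        self.study.truth_table().to_csv(p, sep="\t", index=False, float_format="%.6f")
        paths.append(p)
        self._record("simulate", paths, t0)

    def stage_fdr(self) -> None:
        t0 = time.perf_counter()
        seed = self._seed("fdr")
        mcfg = self.config["mapping"]
        fixed = mcfg.get("thresholds") or {}
        paths = []
        fdir = self.out_dir / "fdr"
        fdir.mkdir(exist_ok=True)
        for k, panel in enumerate(self.panels):
            if panel in fixed:
                self.thresholds[panel] = float(fixed[panel])
                continue
            gm, ts = self.panel_data()[panel]
            expr = ts.traits_of_kind("expression")
            per_condition = []
            for kc, cond in enumerate(ts.conditions):
                table = ts.values[cond].loc[
                    [t for t in expr if t in ts.values[cond].index]
                ]
                fdr = permutation_fdr(
                    table,
                    gm,
                    n_perm=int(mcfg["n_perm"]),
                    seed=np.random.default_rng([seed, k, kc]),
                    target=float(mcfg["fdr_target"]),
                    shared_permutation=bool(mcfg["shared_permutation"]),
                )
                theta = fdr.threshold
                if theta is None:
                    theta = fdr.threshold_at_null_rate(float(mcfg["fdr_target"]))
                per_condition.append(theta)
                p = fdir / f"{panel}_{cond}_fdr.tsv"
                fdr.table.to_csv(p, sep="\t", index=False, float_format="%.6g")
                paths.append(p)
            # one threshold per panel: the strictest across treatments
            self.thresholds[panel] = float(max(per_condition))
        self.manifest["thresholds"] = dict(self.thresholds)
        p = fdir / "thresholds.json"
        with open(p, "w") as fh:
            json.dump(self.thresholds, fh, indent=1, sort_keys=True)
        paths.append(p)
        self._record("fdr", paths, t0)

    def stage_scan(self) -> None:
        t0 = time.perf_counter()
        ccfg = self.config["classification"]
        paths = []
        qdir = self.out_dir / "qtl"
        qdir.mkdir(exist_ok=True)
        for panel in self.panels:
            gm, ts = self.panel_data()[panel]
            expr = ts.traits_of_kind("expression")
            for cond in ts.conditions:
                table = ts.values[cond].loc[
                    [t for t in expr if t in ts.values[cond].index]
                ]
                hits = scan_all_traits(
                    table, gm, threshold=self.thresholds[panel],
                    panel_id=panel, condition=cond,
                )
                classify_hits(
                    hits, ts.annotations,
                    cis_window_mb=float(ccfg["cis_window_mb"]),
                )
                self.hits[(panel, cond)] = hits
                p = qdir / f"{panel}_{cond}_qtl.tsv"
                qio.write_qtl_table([h for h in hits if h.significant], p)
                paths.append(p)
        self._record("scan", paths, t0)

    def stage_patterns(self) -> None:
        t0 = time.perf_counter()
        ccfg = self.config["classification"]
        mode = self.config["patterns"]["mode"]
        probe_flags = {}
        if ccfg.get("probe_flags_file"):
            flags = pd.read_csv(ccfg["probe_flags_file"])
            probe_flags = dict(
                zip(flags.iloc[:, 0].astype(str), flags.iloc[:, 1].astype(bool))
            )
        paths = []
        pdir = self.out_dir / "patterns"
        pdir.mkdir(exist_ok=True)
        data = self.panel_data()
        for panel in self.panels:
            gm, ts = data[panel]
            # union over treatments of significant (trait, marker) pairs,
            # represented by the condition with the highest LRS
            best: dict[tuple[str, str], QTLHit] = {}
            for cond in ts.conditions:
                for h in self.hits[(panel, cond)]:
                    if not h.significant:
                        continue
                    key = (h.trait_id, h.marker_id)
                    if key not in best or h.lrs > best[key].lrs:
                        best[key] = h
            pairs = []
            for (trait, marker), hit in sorted(best.items()):
                vec = lrs_across_conditions(trait, marker, ts, gm)
                pat = make_activity_pattern(
                    vec, self.thresholds[panel], trait_id=trait,
                    marker_id=marker, panel_id=panel, conditions=ts.conditions,
                )
                if pat is not None:
                    pairs.append((hit, pat))
            if self.config["classification"]["probe_snp_filter"].get(panel, False):
                result = filter_probe_snp_cis(pairs, probe_flags, enabled=True)
                pairs = result.kept
            self.patterns_by_panel[panel] = pairs

            other = [p for p in self.panels if p != panel][0]
            other_gm, other_ts = data[other]
            records = [
                cross_population_conservation(
                    hit, pat, other_ts, other_gm, self.thresholds[other], mode=mode
                )
                for hit, pat in pairs
            ]
            self.cross_by_panel[panel] = records

            rows = []
            for (hit, pat), rec in zip(pairs, records):
                row = {
                    "trait": hit.trait_id,
                    "marker": hit.marker_id,
                    "chromosome": hit.chromosome,
                    "position_mb": hit.position_mb,
                    "eqtl_class": hit.eqtl_class,
                    "pattern_index": pat.index,
                    "bits": "".join(map(str, pat.bits)),
                    "conserved_other_panel": rec.conserved_any,
                    "pattern_identical": rec.pattern_identical,
                }
                for cond, v in zip(pat.conditions, pat.lrs_vector):
                    row[f"lrs_{cond}"] = v
                rows.append(row)
            p = pdir / f"{panel}_patterns.tsv"
            pd.DataFrame(rows).to_csv(p, sep="\t", index=False, float_format="%.6g")
            paths.append(p)
            if pairs:
                summary = summarize_patterns(
                    [(hit.eqtl_class, pat) for hit, pat in pairs],
                    n_conditions=len(ts.conditions),
                )
                p = pdir / f"{panel}_class_summary.tsv"
                summary.to_csv(p, sep="\t", float_format="%.6g")
                paths.append(p)
        self._record("patterns", paths, t0)

    def stage_conservation(self) -> None:
        t0 = time.perf_counter()
        ccfg = self.config["conservation"]
        assert self.study is not None
        chrom_lengths = {
            str(k): float(v)
            for k, v in self.config["simulation"].get(
                "chrom_lengths", MOUSE_CHROM_LENGTHS_MB
            ).items()
        }
        paths = []
        cdir = self.out_dir / "conservation"
        cdir.mkdir(exist_ok=True)
        # eQTL track anchored on the second panel (BXD-like), judged in the first
        anchor = self.panels[1] if len(self.panels) > 1 else self.panels[0]
        pairs = self.patterns_by_panel.get(anchor, [])
        records = self.cross_by_panel.get(anchor, [])
        result = {"eqtl_snp_correlation": None}
        if pairs:
            feats = eqtl_feature_table([h for h, _ in pairs], records)
            track_eqtl = sliding_conservation_ratio(
                feats, chrom_lengths,
                window_mb=float(ccfg["window_mb"]), step_mb=float(ccfg["step_mb"]),
            )
            track_snp = sliding_conservation_ratio(
                self.study.snps.table, chrom_lengths,
                window_mb=float(ccfg["window_mb"]), step_mb=float(ccfg["step_mb"]),
            )
            r = track_correlation(track_eqtl, track_snp)
            result = {
                "eqtl_snp_correlation": None if np.isnan(r) else r,
                "eqtl_global_fraction": track_eqtl.global_fraction,
                "snp_global_fraction": track_snp.global_fraction,
            }
            for name, track in (("eqtl", track_eqtl), ("snp", track_snp)):
                p = cdir / f"{name}_track.tsv"
                track.windows.to_csv(p, sep="\t", index=False, float_format="%.6g")
                paths.append(p)
        p = cdir / "correlation.json"
        with open(p, "w") as fh:
            json.dump(result, fh, indent=1, sort_keys=True)
        paths.append(p)
        self._record("conservation", paths, t0)

    def stage_behavior(self) -> None:
        t0 = time.perf_counter()
        seed = self._seed("behavior")
        n_perm = int(self.config["mapping"]["n_perm"])
        rows = []
        data = self.panel_data()
        for k, panel in enumerate(self.panels):
            gm, ts = data[panel]
            for kc, cond in enumerate(ts.conditions):
                for kt, trait in enumerate(ts.traits_of_kind("behavioral")):
                    if trait not in ts.values[cond].index:
                        continue
                    series = ts.values[cond].loc[trait]
                    series.name = trait
                    p, hit = genomewide_pvalue(
                        series, gm, n_perm=n_perm,
                        seed=np.random.default_rng([seed, k, kc, kt]),
                    )
                    rows.append(
                        {
                            "panel": panel, "condition": cond, "trait": trait,
                            "marker": hit.marker_id, "chromosome": hit.chromosome,
                            "position_mb": hit.position_mb, "lrs": hit.lrs,
                            "effect_sign": hit.effect_sign, "p_genomewide": p,
                        }
                    )
        path = self.out_dir / "behavioral_qtl.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")
        self._record("behavior", [path], t0)

    def stage_candidates(self) -> None:
        t0 = time.perf_counter()
        ncfg = self.config["network"]
        paths = []
        cdir = self.out_dir / "candidates"
        cdir.mkdir(exist_ok=True)
        data = self.panel_data()
        for spec in self.config["regions"]:
            region = RegionSpec(
                chromosome=str(spec["chromosome"]),
                start_mb=float(spec["start_mb"]),
                end_mb=float(spec["end_mb"]),
                focal_panel=spec["focal_panel"],
                phenotype_id=spec["phenotype"],
                focal_condition=spec.get("focal_condition", "EC"),
            )
            tag = f"chr{region.chromosome}_{int(region.start_mb)}_{int(region.end_mb)}"
            pairs = self.patterns_by_panel.get(region.focal_panel, [])
            records = self.cross_by_panel.get(region.focal_panel, [])
            region_hits = [
                (pat, rec)
                for (hit, pat), rec in zip(pairs, records)
                if hit.chromosome == region.chromosome
                and region.start_mb <= hit.position_mb <= region.end_mb
            ]
            selected = select_candidates(region_hits)
            p = cdir / f"{tag}_candidates.tsv"
            pd.DataFrame({"trait": selected}).to_csv(p, sep="\t", index=False)
            paths.append(p)
            try:
                graph = build_pattern_network(
                    region, data,
                    prefilter_lrs=float(ncfg["prefilter_lrs"]),
                    include_r=float(ncfg["include_r"]),
                    edge_r=float(ncfg["edge_r"]),
                    panel_order=tuple(self.panels),
                )
            except ValueError as exc:
                log.warning("region %s: no network (%s)", tag, exc)
                continue
            edge_path = cdir / f"{tag}_network.tsv"
            graphml_path = cdir / f"{tag}_network.graphml"
            write_network(graph, edge_path, graphml_path)
            paths.extend([edge_path, graphml_path])
        self._record("candidates", paths, t0)

    # -- driver ------------------------------------------------------------
    def run(self) -> dict[str, Any]:
        for stage in (
            self.stage_simulate, self.stage_fdr, self.stage_scan,
            self.stage_patterns, self.stage_conservation,
            self.stage_behavior, self.stage_candidates,
        ):
            name = stage.__name__.removeprefix("stage_")
            log.info("stage %s ...", name)
            try:
                stage()
            except Exception:
                log.error("stage %s failed", name)
                raise
        path = self.out_dir / "manifest.json"
        with open(path, "w") as fh:
            json.dump(self.manifest, fh, indent=1, sort_keys=True, default=str)
        return self.manifest


def load_panel_data(
    study_dir: str | Path,
    panels: tuple[str, ...] = ("LXS", "BXD"),
    conditions: tuple[str, ...] = ("SC", "EC", "SR", "ER"),
) -> dict[str, tuple[GenotypeMatrix, ConditionedTraitSet]]:
    """Load a study directory written by the ``simulate`` stage back into
    in-memory panel objects."""
    study_dir = Path(study_dir)
    data = {}
    for panel in panels:
        gm = qio.read_geno(study_dir / "genotypes" / f"{panel}.geno", panel_id=panel)
        values = {
            cond: qio.read_trait_table(study_dir / "traits" / f"{panel}_{cond}.csv")
            for cond in conditions
        }
        annotations = pd.read_csv(
            study_dir / "traits" / f"{panel}_annotations.csv",
            index_col=0, dtype={"chromosome": str},
        )
        data[panel] = (
            gm,
            ConditionedTraitSet(
                panel_id=panel, conditions=conditions, values=values,
                annotations=annotations,
            ),
        )
    return data


def run_pipeline(
    config: str | Path | dict | None, out_dir: str | Path
) -> dict[str, Any]:
    """Run the whole pipeline; ``config`` is a YAML path, a dict, or None
    for the built-in demo configuration."""
    if config is None or isinstance(config, (str, Path)):
        cfg = load_config(config)
    else:
        merged = copy.deepcopy(DEFAULT_CONFIG)
        for key, value in config.items():
            if isinstance(value, dict) and isinstance(merged.get(key), dict):
                merged[key].update(value)
            else:
                merged[key] = value
        cfg = merged
    run = PipelineRun(cfg, out_dir)
    return run.run()
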