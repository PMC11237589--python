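"""End-to-end orchestration of the per-stratum network workflow.

One config drives the whole chain: (optional) synthetic community →
abundance filter → alpha/beta diversity and dissimilarity tests →
compositional correlation → signed network, modules, node roles →
stability metrics (robustness, vulnerability, cohesion) → biomarker
scoring. Networks are built per stratum (default: one per genotype ×
condition). Every artifact is a plain TSV/JSON file and the manifest
records parameters, seeds and content hashes so a rerun with the same
config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .abundance import (AbundanceTable, filter_mean_relabund, read_table,
                        to_relative, write_table)
from .biomarkers import lda_effect_size
from .diversity import alpha_diversity, bray_curtis, dissimilarity_tests, pcoa
from .network import (assign_modules, build_network, classify_roles,
                      network_stats, write_network, zi_pi)
from .sparcc import SparccParams, estimate
from .stability import cohesion, simulate_robustness, vulnerability
from .synthetic import CommunityDesign, simulate, write_ground_truth

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and stratum."""


@dataclass
class PipelineConfig:
    # input: either file paths or an inline synthetic design
    table_path: str | None = None
    metadata_path: str | None = None
    synthetic: dict | None = None

    stratify_by: list[str] = field(
        default_factory=lambda: ["genotype", "condition"])
    filter_threshold: float = 1e-4
    filter_per_stratum: bool = True

    sparcc: dict = field(default_factory=dict)     # SparccParams overrides
    p_cut: float = 0.01
    min_abs_rho: float = 0.0

    zi_cut: float = 2.5
    pi_cut: float = 0.62
    role_boundary: str = "strict"
    n_random_rewires: int = 100
    swaps_per_edge: int = 100

    removal_fraction: float = 0.5
    robustness_replicates: int = 100
    cohesion_n_null: int = 200

    biomarker_group_by: str = "condition"
    biomarker_alpha: float = 0.05
    lda_cut: float = 2.0
    lda_n_boot: int = 30

    n_permutations: int = 999
    seed: int = 0
    outdir: str = "rhizonet_out"

    def validate(self) -> None:
        if self.synthetic is None and (self.table_path is None
                                       or self.metadata_path is None):
            raise PipelineError(
                "config needs either table_path+metadata_path or a "
                "synthetic design")
        if not 0 < self.p_cut <= 1:
            raise PipelineError("p_cut must be in (0, 1]")
        if not 0 < self.removal_fraction < 1:
            raise PipelineError("removal_fraction must be in (0, 1)")
        if self.role_boundary not in ("strict", "inclusive"):
            raise PipelineError("role_boundary must be strict|inclusive")
        SparccParams(**{**self.sparcc, "seed": 0})   # validates fields

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str, stratum: str | None = None):
    """Decorator-ish context: re-raise with stage/stratum identity."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                where = f" (stratum {stratum})" if stratum else ""
                raise PipelineError(f"stage {name!r} failed{where}: {exc}"
                                    ) from exc
            return False
    return _Ctx()


def _substream(seed: int, *tags: str) -> int:
    h = hashlib.sha256(("|".join(map(str, (seed,) + tags))).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full workflow; returns the manifest dict (also written to
    ``<outdir>/manifest.json``)."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"rhizonet_version": __version__,
                      "config": asdict(config),
                      "warnings": [], "artifacts": {}, "strata": {}}
    artifacts = manifest["artifacts"]

    def _record(key: str, path: Path) -> None:
        artifacts[key] = {"path": str(path.relative_to(out)),
                          "sha256": _sha256(path)}

    # ---------------- input ----------------
    with _stage("input"):
        if config.synthetic is not None:
            design = CommunityDesign(**{**config.synthetic,
                                        "seed": config.synthetic.get(
                                            "seed", config.seed)})
            table, truth = simulate(design)
            write_table(table, out / "counts.tsv", out / "metadata.tsv")
            write_ground_truth(truth, out / "ground_truth.json",
                               out / "basis_correlation.tsv")
            for key in ("counts.tsv", "metadata.tsv", "ground_truth.json",
                        "basis_correlation.tsv"):
                _record(key, out / key)
        else:
            table = read_table(config.table_path, config.metadata_path)
        missing = [c for c in config.stratify_by
                   if c not in table.metadata.columns]
        if missing:
            raise PipelineError(f"stratification columns absent from "
                                f"metadata: {missing}")

    # ---------------- whole-study diversity ----------------
    with _stage("diversity"):
        alpha = alpha_diversity(table)
        alpha.to_csv(out / "alpha_diversity.tsv", sep="\t",
                     float_format="%.6g")
        _record("alpha_diversity.tsv", out / "alpha_diversity.tsv")

        dm = bray_curtis(table)
        pd.DataFrame(dm.data, index=list(dm.ids),
                     columns=list(dm.ids)).to_csv(
            out / "bray_curtis.tsv", sep="\t", float_format="%.6g")
        _record("bray_curtis.tsv", out / "bray_curtis.tsv")

        coords, eigvals, prop, warns = pcoa(dm, k=2)
        manifest["warnings"].extend(warns)
        coords.to_csv(out / "pcoa.tsv", sep="\t", float_format="%.6g")
        _record("pcoa.tsv", out / "pcoa.tsv")

    with _stage("betatest"):
        strata_labels = table.metadata[config.stratify_by].astype(str).agg(
            "|".join, axis=1).to_numpy()
        if len(np.unique(strata_labels)) >= 2 and (
                pd.Series(strata_labels).value_counts() >= 2).all():
            tests = dissimilarity_tests(
                dm, strata_labels, n_perm=config.n_permutations,
                seed=_substream(config.seed, "betatest"))
            report = {"labels": "|".join(config.stratify_by),
                      "seed": config.seed,
                      "results": [t.as_dict() for t in tests]}
        else:
            report = {"skipped": "fewer than 2 usable strata"}
            manifest["warnings"].append("betatest skipped")
        (out / "dissimilarity_tests.json").write_text(
            json.dumps(report, indent=1, sort_keys=True))
        _record("dissimilarity_tests.json", out / "dissimilarity_tests.json")

    # ---------------- per-stratum network workflow ----------------
    groups = table.metadata.groupby(config.stratify_by, sort=True).groups
    for key, samples in groups.items():
        key_t = key if isinstance(key, tuple) else (key,)
        stratum = "_".join(map(str, key_t))
        sdir = out / f"stratum_{stratum}"
        sdir.mkdir(exist_ok=True)
        srec: dict = {}
        manifest["strata"][stratum] = srec
        if len(samples) < 3:
            srec["skipped"] = "fewer than 3 samples"
            manifest["warnings"].append(f"stratum {stratum} skipped")
            continue

        with _stage("filter", stratum):
            sub = table.subset_samples(list(samples))
            filtered = filter_mean_relabund(sub, config.filter_threshold)
            rel = to_relative(filtered)
            write_table(filtered, sdir / "filtered_counts.tsv")
            _record(f"{stratum}/filtered_counts.tsv",
                    sdir / "filtered_counts.tsv")
            srec["n_taxa_after_filter"] = filtered.n_taxa

        with _stage("cohesion", stratum):
            coh = cohesion(rel, n_null=config.cohesion_n_null,
                           seed=_substream(config.seed, "cohesion", stratum))
            coh.cohesion.to_csv(sdir / "cohesion.tsv", sep="\t",
                                float_format="%.6g")
            _record(f"{stratum}/cohesion.tsv", sdir / "cohesion.tsv")
            srec["mean_neg_pos_ratio"] = float(
                coh.cohesion["neg_pos_ratio"].mean(skipna=True))

        with _stage("correlate", stratum):
            params = SparccParams(**{**config.sparcc,
                                     "seed": _substream(config.seed,
                                                        "sparcc", stratum)})
            est = estimate(filtered, params)
            est.write(sdir / "rho.tsv", sdir / "pvalue.tsv")
            _record(f"{stratum}/rho.tsv", sdir / "rho.tsv")
            _record(f"{stratum}/pvalue.tsv", sdir / "pvalue.tsv")
            srec["sparcc_diagnostics"] = {
                k: v for k, v in est.diagnostics.items()
                if k != "excluded_pairs"}

        with _stage("network", stratum):
            g = build_network(est, rel, p_cut=config.p_cut,
                              min_abs_rho=config.min_abs_rho)
            if g.number_of_nodes() == 0:
                srec["network"] = {"n_nodes": 0, "n_edges": 0}
                manifest["warnings"].append(
                    f"stratum {stratum}: empty network")
                continue
            stats = network_stats(
                g, n_random=config.n_random_rewires,
                swaps_per_edge=config.swaps_per_edge,
                seed=_substream(config.seed, "rewire", stratum))
            srec["network"] = stats.as_dict()
            (sdir / "network_stats.json").write_text(
                json.dumps(stats.as_dict(), indent=1, sort_keys=True))
            _record(f"{stratum}/network_stats.json",
                    sdir / "network_stats.json")

        with _stage("roles", stratum):
            assign_modules(g)
            topo = classify_roles(zi_pi(g), zi_cut=config.zi_cut,
                                  pi_cut=config.pi_cut,
                                  boundary=config.role_boundary)
            write_network(g, sdir / "edges.tsv", sdir / "nodes.tsv",
                          topo=topo)
            _record(f"{stratum}/edges.tsv", sdir / "edges.tsv")
            _record(f"{stratum}/nodes.tsv", sdir / "nodes.tsv")
            srec["n_keystone"] = int(topo["keystone"].sum())

        with _stage("stability", stratum):
            rob = simulate_robustness(
                g, removal_fraction=config.removal_fraction,
                replicates=config.robustness_replicates,
                seed=_substream(config.seed, "robustness", stratum))
            stab: dict = {"robustness": rob.as_dict()}
            if g.number_of_nodes() >= 3:
                try:
                    vul = vulnerability(g)
                    stab["global_efficiency"] = vul.global_efficiency
                    stab["max_vulnerability"] = vul.max_vulnerability
                    vul.node_vulnerability.to_csv(
                        sdir / "vulnerability.tsv", sep="\t",
                        float_format="%.6g")
                    _record(f"{stratum}/vulnerability.tsv",
                            sdir / "vulnerability.tsv")
                except ValueError as exc:
                    manifest["warnings"].append(
                        f"stratum {stratum}: vulnerability undefined ({exc})")
            stab["mean_neg_pos_ratio"] = srec["mean_neg_pos_ratio"]
            (sdir / "stability.json").write_text(
                json.dumps(stab, indent=1, sort_keys=True))
            _record(f"{stratum}/stability.json", sdir / "stability.json")
            srec["stability"] = {k: stab[k] for k in stab
                                 if k != "robustness"}
            srec["stability"]["robustness_mean"] = rob.mean

    # ---------------- biomarkers across the whole study ----------------
    with _stage("biomarkers"):
        labels = table.metadata[config.biomarker_group_by].astype(str)
        counts_ok = labels.value_counts()
        if len(counts_ok) >= 2 and (counts_ok >= 3).all():
            filt_all = filter_mean_relabund(table, config.filter_threshold)
            rel_all = to_relative(filt_all)
            bm = lda_effect_size(
                rel_all, labels.to_numpy(), alpha=config.biomarker_alpha,
                n_boot=config.lda_n_boot, lda_cut=config.lda_cut,
                seed=_substream(config.seed, "biomarkers"))
            bm.table.to_csv(out / "biomarkers.tsv", sep="\t",
                            float_format="%.6g")
            _record("biomarkers.tsv", out / "biomarkers.tsv")
            manifest["n_biomarkers_passing"] = len(bm.passing)
        else:
            manifest["warnings"].append("biomarkers skipped: degenerate "
                                        "grouping")

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
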