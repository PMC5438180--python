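"""End-to-end pipeline: simulate -> filter/bin -> call -> architecture
-> enrichment -> genes -> report.

Every stage consumes and produces files under one run directory so each
can be re-run in isolation; a manifest records SHA-256 and row counts of
every output together with the configuration, making full runs
reproducible hash-for-hash under a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import architecture as arch
from . import calling, enrichment, genes as genemod, hic, simulate
from .genome import RestrictionMap, SyntheticGenome
from .tracks import BinTrack

DEFAULT_CONFIG = {
    "seed": 1,
    "genome": {"n_chroms": 5, "chrom_length": 2_000_000, "site_density": 4.0},
    "tracks": {},
    "hic": {"n_pairs": 200_000, "n_replicates": 3, "decay_alpha": 1.0,
            "inter_frac": 0.05, "loop_frac": 0.08},
    "thresholds": {
        "min_sites": 3, "top_fraction": 0.05, "min_reads": 2,
        "score_cutoffs": [5.0, 10.0, 15.0], "high_confidence_score": 10.0,
        "connection_score": 5.0, "chip_score": 15.0,
        "dmb_ratio": 0.25, "unchanged_ratio": 0.75,
        "mnase_threshold": 2.0, "tf_fold": 4.0,
        "promoter_bp": 1000, "distal_min_sites": 3,
        "surface_min_distance": 10_000, "surface_window": 5000,
    },
    "resolutions": {"bin": 250, "correlation": 25_000, "eigenvector": 100_000},
    "n_perm": 300,
    "surface_n_random": 20,
}


def load_config(path=None, overrides: dict | None = None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        _deep_update(cfg, user)
    if overrides:
        _deep_update(cfg, overrides)
    if "seed" not in cfg or cfg["seed"] is None:
        raise ValueError("config must set an explicit seed")
    return cfg


def _deep_update(base: dict, extra: dict) -> None:
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class Run:
    """One pipeline run rooted at a directory."""

    def __init__(self, outdir, config: dict):
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.config = config
        self.genome: SyntheticGenome | None = None
        self.bundle = None
        self.truth = None
        self.pairs: dict[str, pd.DataFrame] = {}           # raw, per genotype
        self.filtered: dict[str, pd.DataFrame] = {}
        self.calls: dict[str, pd.DataFrame] = {}           # scored simple calls
        self.results: dict = {}

    # -- stages -------------------------------------------------------------

    def stage_simulate(self):
        cfg = self.config
        self.genome = simulate.generate_genome(seed=cfg["seed"], **cfg["genome"])
        tcfg = simulate.TrackConfig(**cfg["tracks"])
        self.bundle, self.truth = simulate.generate_tracks_and_features(
            self.genome, tcfg, seed=cfg["seed"] + 1000)
        h = cfg["hic"]
        for g in self.bundle.genotypes:
            self.pairs[g] = simulate.simulate_replicates(
                self.genome, self.truth, g, h["n_pairs"],
                n_replicates=h["n_replicates"],
                base_seed=cfg["seed"] + 100 * (1 + list(self.bundle.genotypes).index(g)),
                decay_alpha=h["decay_alpha"], inter_frac=h["inter_frac"],
                loop_frac=h["loop_frac"])
        simulate.write_fixture(self.outdir / "fixture", self.genome, self.bundle,
                               self.truth, self.pairs)

    def stage_bin(self):
        thr = self.config["thresholds"]
        res = self.config["resolutions"]
        stats = {}
        for g, pairs in self.pairs.items():
            filt = hic.filter_pairs_by_sites(pairs, self.genome.restriction,
                                             min_sites=thr["min_sites"])
            self.filtered[g] = filt
            stats[g] = {"raw_pairs": len(pairs), "filtered_pairs": len(filt)}
        wt = self.bundle.genotypes[0]
        curve = hic.decay_curve(self.filtered[wt], self.genome.restriction,
                                self.genome, resolution=res["bin"])
        curve.to_csv(self.outdir / "decay_curve.tsv", sep="\t", index=False)
        try:
            stats["decay_exponent"] = hic.fit_decay_exponent(
                curve, self.genome.chrom_sizes)
        except ValueError:
            stats["decay_exponent"] = None
        reps = sorted(self.filtered[wt]["replicate"].unique())
        if len(reps) >= 2:
            a = self.filtered[wt][self.filtered[wt]["replicate"] == reps[0]]
            b = self.filtered[wt][self.filtered[wt]["replicate"] == reps[1]]
            stats["replicate_correlation_25kb"] = hic.replicate_correlation(
                a, b, resolution=res["correlation"])
        self.results["bin"] = stats

    def stage_call(self):
        thr = self.config["thresholds"]
        res = self.config["resolutions"]["bin"]
        info = {}
        for g, filt in self.filtered.items():
            per_rep = []
            for rep, sub in filt.groupby("replicate"):
                binned = hic.bin_pairs(sub, res)
                t = calling.derive_count_threshold(binned, top_fraction=thr["top_fraction"])
                calls = calling.call_simple(binned, t, min_reads=thr["min_reads"])
                calls = calling.score_calls(calls, total_reads=len(sub))
                calls["replicate"] = rep
                per_rep.append(calls)
                info[f"{g}_rep{rep}"] = {"threshold": t.count_threshold,
                                         "n_calls": len(calls)}
            pooled_binned = hic.bin_pairs(filt, res)
            t = calling.derive_count_threshold(pooled_binned,
                                               top_fraction=thr["top_fraction"])
            pooled = calling.call_simple(pooled_binned, t, min_reads=thr["min_reads"])
            pooled = calling.score_calls(pooled, total_reads=len(filt))
            pooled["replicate"] = 0  # 0 marks the combined sample
            self.calls[g] = pd.concat(per_rep + [pooled], ignore_index=True)
            info[f"{g}_pooled"] = {"threshold": t.count_threshold, "n_calls": len(pooled)}
            export_bedpe(self.calls[g], res, self.outdir / f"calls_{g}.bedpe",
                         sample=g)
            with open(self.outdir / f"calls_{g}.json", "w") as fh:
                json.dump({"sample": g, "resolution": res,
                           "thresholds": thr, "stats": info[f"{g}_pooled"]}, fh, indent=1)
        self.results["call"] = info

    def stage_architecture(self):
        res = self.config["resolutions"]
        wt = self.bundle.genotypes[0]
        out = {}
        evs = []
        for chrom in self.genome.chromosomes:
            mat = hic.contact_matrix(self.filtered[wt], res["eigenvector"],
                                     self.genome, chrom)
            try:
                ev = arch.compartment_eigenvector(mat)
            except ValueError:
                continue
            evs.append(pd.DataFrame({"chrom": chrom, "bin": np.arange(ev.size),
                                     "loading": ev}))
        if evs:
            pd.concat(evs, ignore_index=True).to_csv(
                self.outdir / "eigenvector.tsv", sep="\t", index=False)
        pooled = self._pooled_calls(wt)
        meta = arch.telomere_metaplot(pooled, self.genome,
                                      resolution=self.config["resolutions"]["bin"])
        meta.to_csv(self.outdir / "telomere_metaplot.tsv", sep="\t", index=False)
        per_rep = self.calls[wt][self.calls[wt]["replicate"] != 0]
        try:
            cent = arch.centromere_fractions(per_rep, self.genome,
                                             resolution=self.config["resolutions"]["bin"])
            cent.to_csv(self.outdir / "centromere_fractions.tsv", sep="\t", index=False)
            out["centromeric_pct_pooled"] = float(
                cent.loc[cent["sample"] == "pooled", "centromeric_pct"].iloc[0])
        except ValueError:
            out["centromeric_pct_pooled"] = None
        self.results["architecture"] = out

    def _pooled_calls(self, genotype: str, score_cutoff: float | None = None):
        calls = self.calls[genotype]
        pooled = calls[calls["replicate"] == 0]
        if score_cutoff is not None:
            pooled = calling.filter_by_score(pooled, score_cutoff)
        return pooled

    def _replicate_calls(self, genotype: str, score_cutoff: float | None = None):
        calls = self.calls[genotype]
        reps = calls[calls["replicate"] != 0]
        if score_cutoff is not None:
            reps = calling.filter_by_score(reps, score_cutoff)
        return reps

    def stage_enrich(self):
        thr = self.config["thresholds"]
        res = self.config["resolutions"]["bin"]
        bundle = self.bundle
        wt = bundle.genotypes[0]
        mut = bundle.genotypes[1] if len(bundle.genotypes) > 1 else wt
        n_perm = self.config["n_perm"]
        seed = self.config["seed"] + 77

        state = enrichment.classify_chromatin_state(bundle.h3k4me2, bundle.h3k9me2)
        high_chh = enrichment.classify_methylation(bundle.methylation[wt]["meCHH"],
                                                   "meCHH")
        high_chh = high_chh[high_chh["meth_class"] == "high"]
        dmbs = enrichment.classify_dmbs(bundle.methylation[wt]["meCHH"],
                                        bundle.methylation[mut]["meCHH"], high_chh,
                                        dmb_ratio=thr["dmb_ratio"],
                                        unchanged_ratio=thr["unchanged_ratio"])
        dmbs.to_csv(self.outdir / "dmb_classification.tsv", sep="\t", index=False)
        universe = enrichment.mappable_universe(self.genome, bundle.control_coverage,
                                                res)
        cent = self.genome.centromeric_bins(res)
        state_nc = state[~state.apply(lambda r: (r["chrom"], r["bin"]) in cent, axis=1)]

        hc = thr["high_confidence_score"]
        results = {}
        for genotype in (wt, mut):
            calls = pd.concat([self._replicate_calls(genotype, hc)],
                              ignore_index=True)
            for label, bins in (
                    ("active", state_nc[state_nc["chromatin_state"] == "active"]),
                    ("inactive", state_nc[state_nc["chromatin_state"] == "inactive"]),
                    ("dmb", dmbs[dmbs["dmb_status"] == "nrpe1_DMB"]),
                    ("other_mechh", dmbs[dmbs["dmb_status"] == "other_meCHH"])):
                if not len(bins):
                    continue
                r = enrichment.overlap_enrichment(
                    calls, bins[["chrom", "bin"]], universe, n_perm=n_perm,
                    seed=seed, name=f"{genotype}_{label}")
                results[f"{genotype}_{label}"] = {
                    k: r[k] for k in ("observed", "expected", "ratio")} | (
                    {"p_value": r["p_value"]} if "p_value" in r else {})

        dmr_counts = enrichment.dmr_loop_counts(
            {g: self._pooled_calls(g) for g in bundle.genotypes},
            enrichment.mappability_filter(bundle.features["dmrs"],
                                          bundle.control_coverage),
            thr["score_cutoffs"], wild_type=wt, resolution=res)
        dmr_counts.to_csv(self.outdir / "dmr_loop_counts.tsv", sep="\t", index=False)
        results["dmr_loop_ratio"] = {
            g: float(dmr_counts[(dmr_counts["genotype"] == g)
                                & (dmr_counts["score_cutoff"]
                                   == thr["high_confidence_score"])]["ratio_to_wt"].iloc[0])
            for g in bundle.genotypes}
        pd.DataFrame([
            {"comparison": k, **v} for k, v in results.items() if isinstance(v, dict)
            and "ratio" in v
        ]).to_csv(self.outdir / "enrichment.tsv", sep="\t", index=False)
        self.results["enrich"] = results

    def stage_genes(self):
        thr = self.config["thresholds"]
        res = self.config["resolutions"]["bin"]
        bundle = self.bundle
        wt = bundle.genotypes[0]
        mut = bundle.genotypes[1] if len(bundle.genotypes) > 1 else wt
        out = {}
        promoters = genemod.define_promoters(bundle.genes, self.genome.chrom_sizes,
                                             thr["promoter_bp"])
        groups = genemod.expression_groups(bundle.genes, f"rpkm_{wt}")
        stats = genemod.promoter_interaction_stats(
            self._pooled_calls(wt), promoters, groups, res)
        stats.to_csv(self.outdir / "promoter_group_stats.tsv", sep="\t", index=False)
        out["promoter_pct"] = dict(zip(stats["group"], stats["observed_pct"]))

        expr = genemod.expression_by_interaction_level(
            self._pooled_calls(wt), promoters, bundle.genes, f"rpkm_{wt}")
        out["expression_by_signal"] = {
            "median_rpkm": expr["median_rpkm"],
            "p_lowest_vs_highest": expr["p_lowest_vs_highest"]}

        de_genes = bundle.genes[bundle.genes["de_label"] == "up"]["gene_id"].tolist()
        if de_genes:
            conn = genemod.gene_dmr_connections(
                {g: self._pooled_calls(g) for g in bundle.genotypes},
                de_genes, bundle.genes, bundle.features["dmrs"], self.genome,
                wild_type=wt, score_cutoff=thr["connection_score"],
                seed=self.config["seed"] + 5)
            out["gene_dmr_connections"] = {
                "ratios": conn["ratios"], "control_ratios": conn["control_ratios"]}

        surf = genemod.tss_dmr_surface(
            self._pooled_calls(mut), bundle.genes, bundle.features["dmrs"],
            self.genome, window=thr["surface_window"],
            min_distance=thr["surface_min_distance"],
            n_random=self.config["surface_n_random"],
            seed=self.config["seed"] + 6)
        np.savetxt(self.outdir / f"surface_{mut}.tsv", surf.matrix, delimiter="\t")
        out["surface_peak"] = float(surf.matrix.max())
        self.results["genes"] = out

    def stage_report(self):
        summary = self.outdir / "summary.json"
        with open(summary, "w") as fh:
            json.dump(_jsonable(self.results), fh, indent=1, sort_keys=True)
        missing = [s for s in ("bin", "call", "architecture", "enrich", "genes")
                   if s not in self.results]
        if missing:
            raise RuntimeError(f"incomplete run; missing stages: {missing}")
        try:
            self._plot()
        except Exception:  # plotting is best-effort
            pass

    def _plot(self):
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        curve = pd.read_csv(self.outdir / "decay_curve.tsv", sep="\t")
        fig, ax = plt.subplots(figsize=(4, 3))
        c = curve[curve["distance"] > 0]
        ax.loglog(c["distance"], c["count"], ".", ms=2)
        ax.set_xlabel("distance (bp)")
        ax.set_ylabel("pair count")
        fig.tight_layout()
        fig.savefig(self.outdir / "decay_curve.png", dpi=100)
        plt.close(fig)

    # -- driver -------------------------------------------------------------

    STAGES = ("simulate", "bin", "call", "architecture", "enrich", "genes", "report")

    def run_all(self) -> dict:
        for stage in self.STAGES:
            try:
                getattr(self, f"stage_{stage}")()
            except Exception as err:
                self._write_manifest(partial=stage)
                raise RuntimeError(f"stage '{stage}' failed: {err}") from err
        return self._write_manifest()

    def _write_manifest(self, partial: str | None = None) -> dict:
        files = {}
        for p in sorted(self.outdir.rglob("*")):
            if p.is_file() and p.name != "manifest.json" and p.suffix != ".png":
                try:
                    with open(p) as fh:
                        rows = sum(1 for _ in fh)
                except UnicodeDecodeError:
                    rows = None
                files[str(p.relative_to(self.outdir))] = {
                    "sha256": _sha256(p), "rows": rows}
        manifest = {"config": self.config, "files": files}
        if partial:
            manifest["failed_stage"] = partial
        with open(self.outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def export_bedpe(calls: pd.DataFrame, resolution: int, path, sample: str = "") -> None:
    """Write calls as BEDPE: chromA startA endA chromB startB endB name
    score, with sample / method / replicate in extra columns."""
    df = pd.DataFrame({
        "chrom_a": calls["chrom_a"],
        "start_a": calls["bin_a"] * resolution,
        "end_a": (calls["bin_a"] + 1) * resolution,
        "chrom_b": calls["chrom_b"],
        "start_b": calls["bin_b"] * resolution,
        "end_b": (calls["bin_b"] + 1) * resolution,
        "name": [f"call{i}" for i in range(len(calls))],
        "score": calls.get("score", pd.Series(0.0, index=calls.index)),
        "sample": sample,
        "replicate": calls.get("replicate", pd.Series(0, index=calls.index)),
    })
    df.to_csv(path, sep="\t", header=False, index=False)


def run(config: dict, outdir) -> dict:
    """Run the full pipeline; returns the manifest."""
    return Run(outdir, config).run_all()
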