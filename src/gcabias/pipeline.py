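"""End-to-end orchestration: config, staged execution, JSON report.

A run takes a config (YAML or dict), executes whichever stages its inputs
enable — combining-ability estimation from phenotypes, RPKM
quantification, per-hybrid differential calls and bias classification,
per-mark ChIP similarity, sample clustering — and writes per-stage tables
plus one JSON report in which every fraction carries its numerator,
denominator and the thresholds that produced it.  With ``simulate: true``
all inputs are generated synthetically from the seed, which makes a full
run reproducible from the config alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, bias, chip, degtest, diallel, io, quant, synthetic

__all__ = ["PipelineConfig", "run_pipeline", "write_report", "load_config"]


@dataclass
class TrioSpec:
    hybrid: str
    p1: str
    p2: str


@dataclass
class Thresholds:
    fc: float = 2.0
    fdr_expr: float = 0.05
    fdr_chip: float = 0.001
    expressed_rpkm: float = 0.0
    min_chip_count: int = 10

    def __post_init__(self):
        if self.fc <= 0 or self.fdr_expr <= 0 or self.fdr_chip <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class MethodFlags:
    griffing_method: int = 2
    pairing_scheme: str = "pooled-standardized-traits"
    distance: str = "correlation"
    linkage: str = "average"


@dataclass
class PipelineConfig:
    seed: int = 0
    simulate: bool = False
    phenotypes: str | None = None
    counts: str | None = None
    lib_sizes: str | None = None
    gene_models: str | None = None
    gene_models_format: str = "bed"
    trios: list = field(default_factory=list)
    chip_inputs: list = field(default_factory=list)  # {mark, counts, lib_sizes}
    thresholds: Thresholds = field(default_factory=Thresholds)
    methods: MethodFlags = field(default_factory=MethodFlags)

    def __post_init__(self):
        if isinstance(self.thresholds, dict):
            self.thresholds = Thresholds(**self.thresholds)
        if isinstance(self.methods, dict):
            self.methods = MethodFlags(**self.methods)
        self.trios = [TrioSpec(**t) if isinstance(t, dict) else t for t in self.trios]

    def as_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig(**raw)


def _simulated_inputs(cfg: PipelineConfig):
    """Generate a complete synthetic study from the config seed."""
    seed = cfg.seed
    records = []
    for k, (trait, mu, g) in enumerate(
        [
            ("plant_height", 100.0, [6.0, 3.0, 0.0, -3.0, -6.0]),
            ("heading_date", 80.0, [5.0, 2.5, 0.0, -2.5, -5.0]),
            ("grain_number", 150.0, [10.0, 5.0, 0.0, -5.0, -10.0]),
        ]
    ):
        params = synthetic.DiallelSimParams(
            p=5, mu=mu, g=g, sca_sd=1.0, error_sd=2.0, n_env=3, n_rep=3,
            seed=seed + 101 * k, trait=trait,
        )
        records.append(synthetic.simulate_diallel_phenotypes(params))
    phenotypes = pd.concat(records, ignore_index=True)

    trio = synthetic.simulate_trio_counts(
        synthetic.TrioSimParams(seed=seed + 1), return_labels=True
    )
    chip_res = synthetic.simulate_chip_counts(
        trio.models, mark_bias_fraction=0.9, seed=seed + 2
    )
    trios = [TrioSpec(hybrid="F1", p1="P1", p2="P2")]
    chip_data = {"H3K36me3": chip_res}
    return phenotypes, trio.counts, trio.models, trios, chip_data


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Execute all configured stages; write tables under ``outdir``; return the report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "thresholds": asdict(cfg.thresholds),
        "methods": asdict(cfg.methods),
    }

    chip_data: dict = {}
    if cfg.simulate:
        phenotypes, counts, models, trios, chip_data = _simulated_inputs(cfg)
    else:
        phenotypes = io.read_phenotypes(cfg.phenotypes) if cfg.phenotypes else None
        counts = (
            io.read_counts(cfg.counts, cfg.lib_sizes) if cfg.counts else None
        )
        models = None
        if cfg.gene_models:
            reader = io.read_bed if cfg.gene_models_format == "bed" else io.read_gff3
            models = reader(cfg.gene_models)
        trios = cfg.trios
        for entry in cfg.chip_inputs:
            chip_data[entry["mark"]] = io.read_counts(entry["counts"], entry["lib_sizes"])

    if phenotypes is not None:
        report["combining_ability"] = _run_gca(cfg, phenotypes, outdir)
    if counts is not None and models is not None:
        expr = quant.rpkm_matrix(counts, models)
        expr.rename_axis("gene_id").to_csv(outdir / "rpkm.tsv", sep="\t")
        report["expression"] = _run_bias(cfg, counts, expr, trios, outdir)
        Z, labels = bias.cluster_samples(
            expr, distance=cfg.methods.distance, linkage_method=cfg.methods.linkage
        )
        newick = bias.linkage_to_newick(Z, labels)
        (outdir / "dendrogram.nwk").write_text(newick + "\n")
        report["clustering"] = {"newick": newick, "samples": labels}
    if chip_data and models is not None:
        report["chip"] = _run_chip(cfg, chip_data, models, trios, outdir)

    write_report(report, outdir)
    return report


def _run_gca(cfg: PipelineConfig, phenotypes: pd.DataFrame, outdir: Path) -> dict:
    estimator = diallel.gca_method2 if cfg.methods.griffing_method == 2 else diallel.gca_method4
    gca_rows, sca_rows, section = [], [], {}
    for trait in sorted(phenotypes["trait"].unique()):
        means = diallel.cross_means(phenotypes, trait)
        res = estimator(means)
        section[trait] = {
            "mu": res.mu,
            "gca": res.g.to_dict(),
            "method": res.method,
        }
        for parent, val in res.g.items():
            gca_rows.append({"parent": parent, "trait": trait, "gca": val})
        for i, pi in enumerate(res.s.index):
            for pj in res.s.columns[i + 1 :]:
                sca_rows.append(
                    {"cross": f"{pi}x{pj}", "trait": trait, "sca": res.s.loc[pi, pj]}
                )
    pd.DataFrame(gca_rows).to_csv(outdir / "gca.tsv", sep="\t", index=False)
    pd.DataFrame(sca_rows).to_csv(outdir / "sca.tsv", sep="\t", index=False)
    return section


def _run_bias(cfg, counts, expr, trios, outdir: Path) -> dict:
    th = cfg.thresholds
    section = {}
    for trio in trios:
        deg1 = degtest.call_degs(counts, trio.hybrid, trio.p1, th.fc, th.fdr_expr)
        deg2 = degtest.call_degs(counts, trio.hybrid, trio.p2, th.fc, th.fdr_expr)
        deg1.rename_axis("gene_id").to_csv(
            outdir / f"deg_{trio.hybrid}_vs_{trio.p1}.tsv", sep="\t"
        )
        deg2.rename_axis("gene_id").to_csv(
            outdir / f"deg_{trio.hybrid}_vs_{trio.p2}.tsv", sep="\t"
        )
        cls = bias.classify_trio(deg1, deg2, expr, p1=trio.p1, p2=trio.p2, f1=trio.hybrid)
        cls.rename_axis("gene_id").to_csv(
            outdir / f"classification_{trio.hybrid}.tsv", sep="\t"
        )
        expressed = quant.expressed_genes(expr, trio.hybrid, th.expressed_rpkm)
        summary = bias.bias_summary(
            cls,
            frac_similar_p1=bias.similarity_to_parent(deg1, expressed),
            frac_similar_p2=bias.similarity_to_parent(deg2, expressed),
            n_expressed=len(expressed),
            hybrid_id=trio.hybrid,
        )
        d = summary.as_dict()
        d["denominators"] = {
            "similarity": "genes expressed in the hybrid",
            "frac_deg": "genes tested against either parent",
            "categories": "differential trio genes",
            "equal_bias": "equal-to-one-parent genes",
        }
        section[trio.hybrid] = d
    return section


def _run_chip(cfg, chip_data, models, trios, outdir: Path) -> dict:
    th = cfg.thresholds
    section: dict = {}
    mod_sets: dict = {}
    for mark, data in chip_data.items():
        cm = data.counts if isinstance(data, synthetic.ChipSimResult) else data
        mark_sec = {}
        for trio in trios:
            for parent in (trio.p1, trio.p2):
                frac, calls = chip.modification_similarity(
                    cm, trio.hybrid, parent, models,
                    fdr_threshold=th.fdr_chip, min_count=th.min_chip_count,
                )
                calls.rename_axis("gene_id").to_csv(
                    outdir / f"chip_{mark}_{trio.hybrid}_vs_{parent}.tsv", sep="\t"
                )
                mark_sec[f"{trio.hybrid}_vs_{parent}"] = {
                    "fraction_similar": frac,
                    "n_universe": int(len(calls)),
                    "fdr_threshold": th.fdr_chip,
                }
            signal = chip.gene_body_rpkm(cm, models)
            mod_sets[mark] = chip.modified_gene_set(
                signal, trio.hybrid, counts=cm, min_count=th.min_chip_count
            )
        section[mark] = mark_sec
    marks = sorted(mod_sets)
    if len(marks) == 2:
        section["overlap"] = chip.mark_overlap(mod_sets[marks[0]], mod_sets[marks[1]])
    return section


def write_report(report: dict, outdir) -> Path:
    """Serialize the report bundle; every section must already be JSON-safe."""
    outdir = Path(outdir)
    path = outdir / "report.json"
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    lines = [f"gcabias {report['version']} (seed {report['seed']})"]
    for hybrid, d in report.get("expression", {}).items():
        lines.append(
            f"{hybrid}: {d['frac_deg']:.1%} DEG of {d['n_tested']} tested; "
            f"similar to P1 {d['frac_similar_p1']:.1%}, P2 {d['frac_similar_p2']:.1%}"
        )
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
    return path
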