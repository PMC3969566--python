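"""End-to-end orchestration: polymorphism -> tree -> selection ->
specificity -> population, from one configuration.

Every stage is a pure function of its inputs and the seed, so a rerun
with the same configuration produces a byte-identical JSON report.  Stage
failures propagate with the stage name attached.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import codon_selection as cs
from . import phylogeny, polymorphism, population_stats, specificity
from .io_annotation import RegionAnnotation, extract_orf, read_fasta, translate

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs and knobs for a full analysis run."""

    fasta: Path
    annotation: Path
    matrix: Path | None = None
    counts: Path | None = None
    plasmid: Path | None = None
    models: tuple[str, ...] = ("M0", "M1", "M2", "M7", "M8")
    distance_model: str = "k2p"
    bootstrap_replicates: int = 1000
    freqs: str = "f3x4"
    seed: int = 0
    output_dir: Path = Path("hetsel_out")

    def __post_init__(self) -> None:
        for attr in ("fasta", "annotation", "matrix", "counts", "plasmid"):
            value = getattr(self, attr)
            if value is None:
                continue
            value = Path(value)
            setattr(self, attr, value)
            if not value.exists():
                raise FileNotFoundError(f"{attr} input does not exist: {value}")
        unknown = set(self.models) - set(cs.MODELS)
        if unknown:
            raise ValueError(f"unimplemented models requested: {sorted(unknown)}")
        self.output_dir = Path(self.output_dir)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "models" in raw:
            raw["models"] = tuple(raw["models"])
        return cls(**raw)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as err:  # noqa: BLE001 - annotate and re-raise
                raise StageError(name, err) from err
            log.info("stage %s finished in %.2f s", name, time.perf_counter() - t0)
            return out

        return wrapped

    return deco


@_stage("polymorphism")
def _run_polymorphism(alleles, ann):
    table = polymorphism.polymorphic_sites(alleles, ann)
    orf = extract_orf(alleles, ann)
    classified = polymorphism.classify_coding_sites(table, orf, ann)
    proteins = translate(orf)
    ptable = polymorphism.protein_variants(proteins)
    return classified, ptable, proteins, orf, polymorphism.summarize(classified, ptable)


@_stage("tree")
def _run_tree(alleles, cfg: RunConfig):
    return phylogeny.bootstrap_support(
        alleles, replicates=cfg.bootstrap_replicates, seed=cfg.seed,
        model=cfg.distance_model,
    )


@_stage("selection")
def _run_selection(orf, tree, cfg: RunConfig):
    fits = cs.fit_model_series(
        orf, tree, models=cfg.models, freqs=cfg.freqs, seed=cfg.seed
    )
    lrts = {}
    for null, alt in (("M1", "M2"), ("M7", "M8")):
        if null in fits and alt in fits:
            r = cs.likelihood_ratio_test(fits[null], fits[alt])
            lrts[f"{null}_vs_{alt}"] = {
                "statistic": round(r.statistic, 4),
                "df": r.df,
                "p_value": float(f"{r.p_value:.4g}"),
            }
    neb = None
    flagged = {}
    for model in ("M2", "M8", "M3k3"):
        if model in fits:
            neb = cs.neb_sites(fits[model], orf)
            flagged = {
                "model": model,
                "selected_0.99": cs.positively_selected_sites(neb, 0.99),
                "selected_0.95": cs.positively_selected_sites(neb, 0.95),
            }
            break
    return fits, lrts, neb, flagged


@_stage("specificity")
def _run_specificity(matrix, ptable):
    classes = specificity.partition_classes(matrix)
    rules = specificity.implication_rules(matrix)
    minimal = specificity.minimal_discriminating_set(ptable, classes)
    determinants = specificity.determinant_positions(ptable, classes)
    return classes, rules, minimal, determinants


@_stage("population")
def _run_population(sample, classes, matrix, plasmid, cfg: RunConfig):
    out = {
        "n": sample.total,
        "allele_frequencies": {
            a: round(f, 4) for a, f in sorted(sample.frequencies().items())
        },
        "class_frequencies": {
            c: round(f, 4)
            for c, f in population_stats.class_frequencies(sample, classes).items()
        },
    }
    rho, p = population_stats.reaction_count_association(sample, matrix)
    out["reaction_count_association"] = {
        "spearman_rho": round(rho, 4), "p_value": float(f"{p:.4g}")
    }
    if plasmid is not None:
        table, pv = population_stats.plasmid_association(
            plasmid, classes, seed=cfg.seed
        )
        out["plasmid_association"] = {
            "table": {str(k): [int(x) for x in row] for k, row in
                      zip(table.index, table.to_numpy())},
            "p_value": float(f"{pv:.4g}"),
        }
    return out


def run_all(cfg: RunConfig) -> dict:
    """Execute every configured stage and write the report bundle.

    Returns the machine-readable summary that is also written as
    ``report.json`` in the output directory.
    """
    cfg.output_dir.mkdir(parents=True, exist_ok=True)
    alleles = read_fasta(cfg.fasta)
    ann = RegionAnnotation.from_yaml(cfg.annotation)

    classified, ptable, proteins, orf, summary = _run_polymorphism(alleles, ann)
    tree = _run_tree(alleles, cfg)
    fits, lrts, neb, flagged = _run_selection(orf, tree, cfg)

    report: dict = {
        "seed": cfg.seed,
        "n_alleles": len(alleles),
        "alignment_length": alleles.length,
        "polymorphism": summary,
        "tree_newick": tree.newick(),
        "models": {m: f.summary() for m, f in fits.items()},
        "lrt": lrts,
        "positively_selected": flagged,
    }

    if cfg.matrix is not None:
        matrix = specificity.IncompatibilityMatrix.from_tsv(cfg.matrix)
        classes, rules, minimal, determinants = _run_specificity(matrix, ptable)
        report["specificity"] = {
            "n_classes": len(classes),
            "classes": classes.as_dict(),
            "strict_rules": [
                f"{r.antecedent} => {r.consequent}" for r in rules if r.strict
            ],
            "minimal_discriminating_set": minimal,
            "causal_determinants": sorted(
                {d.position for d in determinants if d.causal}
            ),
        }
        if cfg.counts is not None:
            sample = population_stats.PopulationSample.from_tsv(cfg.counts)
            plasmid = (
                population_stats.PlasmidTable.from_tsv(cfg.plasmid)
                if cfg.plasmid is not None
                else None
            )
            report["population"] = _run_population(
                sample, classes, matrix, plasmid, cfg
            )

    classified.to_csv(cfg.output_dir / "polymorphic_sites.tsv", sep="\t", index=False)
    ptable.to_csv(cfg.output_dir / "protein_variants.tsv", sep="\t", index=False)
    if neb is not None:
        neb.to_csv(cfg.output_dir / "neb_posteriors.tsv", sep="\t", index=False)
    (cfg.output_dir / "tree.nwk").write_text(tree.newick() + "\n")
    with open(cfg.output_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
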