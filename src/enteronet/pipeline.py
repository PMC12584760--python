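"""End-to-end orchestration of the cohort analysis workflow.

Stage order mirrors the study design: simulate (or load) the cohort →
enterotype discovery → phenotype comparison → diversity → differential
taxa → co-occurrence networks per enterotype → genus–phenotype
associations. Every run writes a JSON manifest recording package
version, stage parameters, seeds, and SHA-256 checksums of all outputs,
so a rerun with the same configuration is verifiably bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .association import associate
from .differential import compare_features, compare_phenotypes
from .diversity import alpha_diversity, anosim, bray_curtis
from .enterotypes import pcoa, select_enterotypes
from .io_tables import (
    AbundanceTable,
    PhenotypeTable,
    filter_by_detection,
    filter_taxa,
    read_table,
    write_table,
)
from .network import build_rmt_network, export_network, spearman_network
from .simulate import SimConfig, generate_cohort, multinomial_counts

__all__ = ["RunConfig", "run_pipeline", "load_config"]

ALL_STAGES = (
    "simulate",
    "enterotype",
    "diversity",
    "differential",
    "network_genus",
    "network_rmt",
    "association",
)

log = logging.getLogger("enteronet")


@dataclass
class RunConfig:
    """Pipeline configuration; every random stage carries its own seed."""

    out_dir: str = "enteronet_run"
    stages: tuple[str, ...] = ALL_STAGES
    # input: either a SimConfig (simulate stage) or paths to tables
    sim: SimConfig | None = None
    abundance_path: str | None = None
    phenotype_path: str | None = None
    # stage parameters
    pseudocount: float = 1e-6
    k_min: int = 2
    k_max: int = 10
    anosim_permutations: int = 999
    anosim_seed: int = 1
    q_cutoff: float = 0.05
    genus_min_abund: float = 0.005
    genus_min_prev: float = 0.5
    genus_alpha: float = 0.05
    rmt_min_detection: float = 0.6
    rmt_t_min: float = 0.3
    rmt_t_max: float = 0.95
    rmt_step: float = 0.01
    association_alpha: float = 0.05
    quiet: bool = False

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        if self.sim is None and "simulate" in self.stages:
            self.sim = SimConfig()
        if self.sim is None and self.abundance_path is None:
            raise ValueError("need either a simulate stage or an abundance_path")


def load_config(path) -> RunConfig:
    """Read a YAML run configuration; the ``sim`` mapping becomes a SimConfig."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = raw.pop("sim", None)
    cfg = RunConfig(**raw)
    if sim is not None:
        cfg.sim = SimConfig(**sim)
    if "stages" in raw or isinstance(cfg.stages, list):
        cfg.stages = tuple(cfg.stages)
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; return the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not config.quiet:
        logging.basicConfig(stream=sys.stderr, level=logging.INFO, force=True)

    manifest: dict = {
        "package": "enteronet",
        "version": __version__,
        "stages": {},
        "outputs": {},
        "seeds": {},
    }
    outputs: list[Path] = []

    def record(stage: str, params: dict, files: list[Path]) -> None:
        manifest["stages"][stage] = params
        outputs.extend(files)

    def timed(stage):
        start = time.perf_counter()
        log.info("stage %s started", stage)
        return lambda: log.info(
            "stage %s finished in %.2fs", stage, time.perf_counter() - start
        )

    abundance: AbundanceTable | None = None
    counts: AbundanceTable | None = None
    phenotypes: PhenotypeTable | None = None
    enterotype_labels: pd.Series | None = None

    if "simulate" in config.stages:
        done = timed("simulate")
        sim = config.sim
        abundance, phenotypes, truth = generate_cohort(sim)
        counts = multinomial_counts(abundance, sim.count_depth, sim.seed + 1)
        files = [
            out / "abundance.tsv", out / "counts.tsv", out / "phenotypes.tsv",
            out / "truth_samples.tsv", out / "truth_taxa.tsv",
        ]
        write_table(abundance, files[0])
        write_table(counts, files[1])
        write_table(phenotypes, files[2])
        truth.write(files[3], files[4])
        manifest["seeds"]["simulate"] = sim.seed
        record("simulate", dataclasses.asdict(sim), files)
        done()
    else:
        abundance = read_table(config.abundance_path, kind="abundance")
        if config.phenotype_path:
            phenotypes = read_table(config.phenotype_path, kind="phenotype")

    try:
        if "enterotype" in config.stages:
            done = timed("enterotype")
            res = select_enterotypes(
                abundance,
                k_range=range(config.k_min, config.k_max + 1),
                pseudocount=config.pseudocount,
            )
            enterotype_labels = res.assignment
            assign = res.assignment.rename("enterotype").to_frame()
            assign.index.name = "sample_id"
            assign.to_csv(out / "enterotypes.tsv", sep="\t", lineterminator="\n")
            ch = pd.DataFrame(
                {"k": list(res.ch_scores), "ch": list(res.ch_scores.values())}
            )
            ch.to_csv(out / "ch_curve.tsv", sep="\t", index=False, lineterminator="\n")
            from .enterotypes import jsd_matrix

            D = jsd_matrix(abundance, pseudocount=config.pseudocount)
            ord_res = pcoa(D, n_axes=2)
            coords = ord_res.coordinates.copy()
            coords.index.name = "sample_id"
            coords.to_csv(out / "pcoa.tsv", sep="\t", lineterminator="\n")
            record(
                "enterotype",
                {
                    "k_min": config.k_min, "k_max": config.k_max,
                    "pseudocount": config.pseudocount, "k_selected": res.k_selected,
                },
                [out / "enterotypes.tsv", out / "ch_curve.tsv", out / "pcoa.tsv"],
            )
            done()

        if "diversity" in config.stages and enterotype_labels is not None:
            done = timed("diversity")
            alpha_tbl = alpha_diversity(counts) if counts is not None else alpha_diversity(abundance)
            alpha_tbl.index.name = "sample_id"
            alpha_tbl.to_csv(out / "alpha_diversity.tsv", sep="\t", lineterminator="\n")
            bc = bray_curtis(abundance)
            an = anosim(
                bc,
                enterotype_labels,
                n_permutations=config.anosim_permutations,
                seed=config.anosim_seed,
            )
            pd.DataFrame(
                [dataclasses.asdict(an)]
            ).to_csv(out / "anosim.tsv", sep="\t", index=False, lineterminator="\n")
            manifest["seeds"]["anosim"] = config.anosim_seed
            record(
                "diversity",
                {"permutations": config.anosim_permutations, "anosim_R": an.r_statistic,
                 "anosim_p": an.p_value},
                [out / "alpha_diversity.tsv", out / "anosim.tsv"],
            )
            done()

        if "differential" in config.stages and enterotype_labels is not None:
            done = timed("differential")
            diff = compare_features(abundance, enterotype_labels, q_cutoff=config.q_cutoff)
            diff.to_csv(out / "differential_taxa.tsv", sep="\t", lineterminator="\n")
            files = [out / "differential_taxa.tsv"]
            if phenotypes is not None:
                pdiff = compare_phenotypes(phenotypes, enterotype_labels)
                pdiff.to_csv(out / "differential_phenotypes.tsv", sep="\t", lineterminator="\n")
                files.append(out / "differential_phenotypes.tsv")
            record("differential", {"q_cutoff": config.q_cutoff}, files)
            done()

        if "network_genus" in config.stages and enterotype_labels is not None:
            done = timed("network_genus")
            # genera selected on all samples, correlations within each cluster
            selected = filter_taxa(
                abundance, config.genus_min_abund, config.genus_min_prev
            )
            files = []
            for cluster in sorted(enterotype_labels.unique()):
                members = enterotype_labels[enterotype_labels == cluster].index
                sub = AbundanceTable(
                    selected.data.loc[members], rank=selected.rank
                )
                net = spearman_network(sub, alpha=config.genus_alpha)
                paths = export_network(net, out, prefix=f"genus_network_c{cluster}")
                files.extend(paths.values())
            record(
                "network_genus",
                {"min_abund": config.genus_min_abund, "min_prev": config.genus_min_prev,
                 "alpha": config.genus_alpha},
                files,
            )
            done()

        if "network_rmt" in config.stages and enterotype_labels is not None:
            done = timed("network_rmt")
            files = []
            for cluster in sorted(enterotype_labels.unique()):
                members = enterotype_labels[enterotype_labels == cluster].index
                sub = filter_by_detection(
                    AbundanceTable(abundance.data.loc[members], rank=abundance.rank),
                    config.rmt_min_detection,
                )
                net = build_rmt_network(
                    sub, t_min=config.rmt_t_min, t_max=config.rmt_t_max,
                    step=config.rmt_step,
                )
                paths = export_network(net, out, prefix=f"rmt_network_c{cluster}")
                files.extend(paths.values())
                if net.threshold_scan is not None:
                    scan_path = out / f"rmt_scan_c{cluster}.tsv"
                    net.threshold_scan.to_frame().to_csv(
                        scan_path, sep="\t", index=False, lineterminator="\n"
                    )
                    files.append(scan_path)
            record(
                "network_rmt",
                {"min_detection": config.rmt_min_detection,
                 "t_min": config.rmt_t_min, "t_max": config.rmt_t_max,
                 "step": config.rmt_step},
                files,
            )
            done()

        if (
            "association" in config.stages
            and enterotype_labels is not None
            and phenotypes is not None
        ):
            done = timed("association")
            diff = compare_features(abundance, enterotype_labels, q_cutoff=config.q_cutoff)
            significant = [
                f for f, row in diff.iterrows() if row["enriched_in"] is not None
            ]
            taxa = significant if significant else None
            assoc = associate(
                abundance, phenotypes, taxa_subset=taxa, alpha=config.association_alpha
            )
            assoc.to_long().to_csv(
                out / "associations.tsv", sep="\t", index=False, lineterminator="\n"
            )
            record(
                "association",
                {"alpha": config.association_alpha, "n_taxa": len(assoc.rho)},
                [out / "associations.tsv"],
            )
            done()
    except Exception as exc:
        # retain partial outputs; name the failing stage
        stage = list(manifest["stages"])[-1] if manifest["stages"] else "setup"
        raise RuntimeError(f"pipeline failed after stage {stage!r}: {exc}") from exc

    manifest["outputs"] = {str(p.name): _sha256(p) for p in outputs}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
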