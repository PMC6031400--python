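"""End-to-end orchestration: simulate -> primer eval -> calibrate ->
cluster -> diversity/overlap/ranking/novelty -> qPCR/rates/correlation.

``run_pipeline`` executes the full analysis on a simulated study and
writes a JSON report plus TSV side-tables.  The report is a pure
function of (config, seed): rerunning with the same config yields an
identical report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import abundance_rates as ar
from . import otu_pipeline as op
from . import synthetic_data as sd
from . import threshold_calibration as tc
from .io import write_fasta, write_tsv
from .primer_tools import L2F_V1, URE_733R, degeneracy, primer_coverage

logger = logging.getLogger("ureotype")

__all__ = ["PipelineConfig", "run_pipeline"]

_STAGE_DEFAULTS: dict[str, dict[str, Any]] = {
    "primer_eval": {"max_mismatch": 1},
    "calibration": {"reference_identity": 99.0, "mode": "regression",
                    "injected_values": None},
    "clustering": {"threshold": 91.0, "min_len": 200, "max_n_fraction": 0.0},
    "ranking": {"top_n": 34},
    "novelty": {"threshold": 91.0},
    "report": {"round_decimals": 1},
}


@dataclasses.dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    ``simulate`` holds SimConfig fields; the other blocks mirror each
    stage's knobs.  Unknown keys anywhere are rejected.
    """

    seed: int = 0
    outdir: str = "ureotype_out"
    simulate: sd.SimConfig = dataclasses.field(default_factory=sd.SimConfig)
    stages: dict[str, dict[str, Any]] = dataclasses.field(
        default_factory=lambda: {k: dict(v) for k, v in _STAGE_DEFAULTS.items()})

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        raw = dict(raw)
        known_top = {"seed", "outdir", "simulate"} | set(_STAGE_DEFAULTS)
        unknown = set(raw) - known_top
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        seed = int(raw.pop("seed", 0))
        outdir = raw.pop("outdir", "ureotype_out")
        sim_block = dict(raw.pop("simulate", {}))
        sim_fields = {f.name for f in dataclasses.fields(sd.SimConfig)}
        bad = set(sim_block) - sim_fields
        if bad:
            raise ValueError(f"unknown simulate keys: {sorted(bad)}")
        for key in ("amplicon_window", "divergence_grid", "copies_16s_range",
                    "urec_fraction_range", "kinetics_times_h"):
            if key in sim_block and isinstance(sim_block[key], list):
                sim_block[key] = tuple(sim_block[key])
        sim_block["seed"] = seed
        stages = {k: dict(v) for k, v in _STAGE_DEFAULTS.items()}
        for name, block in raw.items():
            bad = set(block) - set(_STAGE_DEFAULTS[name])
            if bad:
                raise ValueError(f"unknown keys in stage {name!r}: {sorted(bad)}")
            stages[name].update(block)
        return cls(seed=seed, outdir=outdir,
                   simulate=sd.SimConfig(**sim_block), stages=stages)


def _round_floats(obj: Any, nd: int = 4) -> Any:
    if isinstance(obj, float):
        return round(obj, nd)
    if isinstance(obj, dict):
        return {k: _round_floats(v, nd) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, nd) for v in obj]
    return obj


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute every stage and write the report bundle to config.outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "provenance": {
            "seed": config.seed,
            "simulate": dataclasses.asdict(config.simulate),
            "stages": config.stages,
        }
    }

    stage = "simulate"
    try:
        study = sd.simulate_study(config.simulate)
        report["simulate"] = {
            "n_genomes": len(study.genomes),
            "n_sites": len(study.reads),
            "reads_per_site": config.simulate.reads_per_site,
            "true_core_otus": sorted(study.true_core_otus),
        }
        for site, reads in study.reads.items():
            write_fasta(outdir / f"{site}_ureC_reads.fasta", reads)
        prov = pd.DataFrame(sorted(study.provenance.items()),
                            columns=["read_id", "genome_id"])
        write_tsv(prov, outdir / "read_provenance.tsv", index=False)

        stage = "primer_eval"
        pe = config.stages["primer_eval"]
        templates = {g.genome_id: g.seq_urec for g in study.genomes}
        cov = primer_coverage(L2F_V1, URE_733R, templates,
                              max_mismatch=pe["max_mismatch"])
        report["primer_eval"] = {
            "primer_pair": list(cov.primer_pair),
            "fwd_degeneracy": degeneracy(L2F_V1),
            "rev_degeneracy": degeneracy(URE_733R),
            "max_mismatch": pe["max_mismatch"],
            "n_templates": cov.n_templates,
            "n_amplifiable": cov.n_amplifiable,
            "coverage": cov.coverage,
        }
        write_tsv(pd.DataFrame(cov.detail), outdir / "primer_coverage.tsv",
                  index=False)

        stage = "calibration"
        cal = config.stages["calibration"]
        ref = cal["reference_identity"]
        if cal["injected_values"]:
            per_lineage = {f"lineage{i+1}": float(v)
                           for i, v in enumerate(cal["injected_values"])}
        else:
            per_lineage = {}
            by_lineage: dict[str, list[tc.MarkerPairRecord]] = {}
            for g in study.genomes:
                by_lineage.setdefault(g.lineage, []).append(g)
            for lineage, members in sorted(by_lineage.items()):
                query, subjects = members[0], members[1:]
                points, _ = tc.build_identity_points(query, subjects)
                value, _diag = tc.calibrate_lineage(points, ref, cal["mode"])
                per_lineage[lineage] = value
        result = tc.combine_calibrations(per_lineage, ref)
        report["calibration"] = {
            "per_lineage": result.per_lineage,
            "reference_identity": result.reference_identity,
            "mean_identity": result.mean_identity,
            "conservative_threshold": result.conservative_threshold,
        }

        stage = "clustering"
        cl = config.stages["clustering"]
        readsets = [op.ReadSet(site, reads) for site, reads in study.reads.items()]
        filtered, logs = [], {}
        for rs in readsets:
            f, lg = op.quality_filter(rs, cl["min_len"], cl["max_n_fraction"])
            filtered.append(f)
            logs[rs.sample_id] = lg
        uniques = op.dereplicate(filtered)
        otus = op.greedy_cluster(uniques, cl["threshold"])
        table = op.build_otu_table(otus, [rs.sample_id for rs in filtered],
                                   cl["threshold"])
        report["clustering"] = {
            "threshold": cl["threshold"],
            "filter_log": logs,
            "n_uniques": len(uniques),
            "n_otus": len(otus),
            "per_sample_richness": {
                s: int((table.counts.loc[s] > 0).sum()) for s in table.samples},
        }
        write_tsv(table.counts, outdir / "otu_table.tsv")
        write_fasta(outdir / "otu_representatives.fasta",
                    sorted(table.representatives.items()))

        stage = "diversity"
        stats = op.diversity_stats(table)
        report["diversity"] = {
            s.sample_id: {"n_reads": s.n_reads, "richness": s.richness,
                          "singletons": s.singletons,
                          "goods_coverage": s.goods_coverage}
            for s in stats}
        rows = [{"sample": s.sample_id, "depth": d, "expected_richness": r}
                for s in stats for d, r in s.rarefaction_curve]
        write_tsv(pd.DataFrame(rows), outdir / "rarefaction.tsv", index=False)

        stage = "shared"
        core, specific_counts, _ = op.shared_otus(table)
        report["shared"] = {
            "n_otus_total": len(table.otu_ids),
            "core_otus": sorted(core),
            "n_core": len(core),
            "site_specific_counts": specific_counts,
            "n_site_specific": int(sum(specific_counts.values())),
        }

        stage = "ranking"
        top = op.rank_otus(table, config.stages["ranking"]["top_n"])
        write_tsv(top, outdir / "top_otus.tsv")
        report["ranking"] = {"top_n": int(len(top)),
                             "top_otu_ids": list(top.index[:5])}

        stage = "novelty"
        nov = config.stages["novelty"]
        reference = {g.genome_id: sd._amplicon(g, config.simulate)
                     for g in study.genomes}
        top_otus = [o for o in otus if o.otu_id in set(top.index)]
        ncls = op.novelty_classification(top_otus, reference, nov["threshold"])
        write_tsv(ncls, outdir / "novelty.tsv")
        report["novelty"] = {
            "threshold": nov["threshold"],
            "n_classified": int(len(ncls)),
            "n_below_threshold": int(ncls["below_threshold"].sum()),
        }

        stage = "qpcr"
        sites = sorted(study.reads)
        curve = study.standard_curve
        abund = {}
        simc = config.simulate
        for site in sites:
            a16 = ar.quantify(study.qpcr_cq[site]["16S"], curve,
                              simc.elution_volume_uL, simc.template_volume_uL,
                              simc.extraction_dry_mass_g, site, "16S")
            aur = ar.quantify(study.qpcr_cq[site]["ureC"], curve,
                              simc.elution_volume_uL, simc.template_volume_uL,
                              simc.extraction_dry_mass_g, site, "ureC")
            rel = ar.relative_abundance(aur, a16)
            abund[site] = {"copies_16s": a16.copies_per_g_dry,
                           "copies_urec": aur.copies_per_g_dry,
                           "relative_abundance_pct": rel}
        report["qpcr"] = abund

        stage = "rates"
        rates = {site: ar.ureolysis_rate(study.kinetics[site]) for site in sites}
        report["rates"] = {
            site: {"rate": r.rate, "se": r.se, "r_squared": r.fit_r_squared,
                   "points_used": r.points_used, "caveat": r.caveat}
            for site, r in rates.items()}

        stage = "correlate"
        rate_vec = [rates[s].rate for s in sites]
        corr = {}
        for gene, key in (("16S", "copies_16s"), ("ureC", "copies_urec")):
            r, r2, p = ar.correlate([abund[s][key] for s in sites], rate_vec)
            corr[gene] = {"pearson_r": r, "r_squared": r2, "p_value": p}
        report["correlation"] = corr
    except Exception as exc:
        partial = outdir / "report.json.partial"
        partial.write_text(json.dumps(_round_floats(report), indent=2,
                                      sort_keys=True))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (outdir / "report.json").write_text(
        json.dumps(_round_floats(report), indent=2, sort_keys=True))
    logger.info("pipeline complete: %s", outdir / "report.json")
    return report
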