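"""End-to-end orchestration and packaged fixtures.

``run_full`` executes the whole analysis in the order of the study:
residue partition -> 25-feature enrichment (DR vs NR) -> variant burden ->
intolerance calls -> enrichment over intolerant-vs-tolerant IDR residues ->
permutation feature importance; one TSV per stage plus a JSON summary of
the headline statistics. Runs are fully deterministic given the config.

The packaged fixtures are the published table of 34 mutation-intolerant
IDRs with their per-type pathogenic/population counts, and the two printed
residue-level 2x2 tables (missense/synonymous and active-peptide).
"""

from __future__ import annotations

import dataclasses
import hashlib
import io
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from . import annotation_model as am
from . import feature_enrichment as fe
from . import importance as imp
from . import intolerance as it
from . import variant_burden as vb
from .annotation_model import PROTEIN_CHANGING_TYPES, DisorderRegion, ResiduePartition
from .feature_enrichment import ContingencyTable
from .variant_burden import RegionVariantCounts

_FIXTURE_SHA256 = {
    "table1_counts.tsv": "b68d52fb98a309608f4550f049cdef3baab8874bfc0f08e26c4c29ca7a04c3b4",
    "printed_2x2.tsv": "85933ae41081c05d301eee4c459eebd9d07b633d88481593d29ae45efd1e956e",
}


def _fixture_text(name: str) -> str:
    data = resources.files("idrconstraint.data").joinpath(name).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _FIXTURE_SHA256[name]:
        raise RuntimeError(f"fixture {name} checksum mismatch: {digest}")
    return data.decode()


def load_table1_fixture() -> tuple[list[RegionVariantCounts], list[DisorderRegion]]:
    """The 34 published mutation-intolerant IDRs with their count columns."""
    df = pd.read_csv(io.StringIO(_fixture_text("table1_counts.tsv")), sep="\t")
    counts: list[RegionVariantCounts] = []
    regions: list[DisorderRegion] = []
    for row in df.itertuples(index=False):
        counts.append(
            RegionVariantCounts(
                region_id=row.region_id,
                pathogenic={
                    v: int(getattr(row, f"{v}_pathogenic")) for v in PROTEIN_CHANGING_TYPES
                },
                population={
                    v: int(getattr(row, f"{v}_population")) for v in PROTEIN_CHANGING_TYPES
                },
            )
        )
        regions.append(
            DisorderRegion(
                region_id=row.region_id,
                accession=row.gene,
                gene=row.gene,
                start=int(row.start),
                end=int(row.end),
            )
        )
    return counts, regions


def load_printed_2x2() -> dict[str, ContingencyTable]:
    """The published residue-level 2x2 count tables, keyed by name."""
    df = pd.read_csv(io.StringIO(_fixture_text("printed_2x2.tsv")), sep="\t")
    return {
        row.name: ContingencyTable(int(row.a), int(row.b), int(row.c), int(row.d))
        for row in df.itertuples(index=False)
    }


# ---------------------------------------------------------------------------
# Full pipeline


@dataclass
class RunConfig:
    proteins: str
    regions: str
    features: str
    variants: str
    out_dir: str
    alpha: float = 0.05
    bonferroni_m: int = 25
    intolerance_mode: str = "non_strict"
    thresholds: str = "recompute"  # recompute | published
    importance_seed: int = 7
    importance_repeats: int = 10

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _intolerant_tolerant_partition(
    regions: list[DisorderRegion],
    calls: list[it.IntoleranceCall],
    partition: ResiduePartition,
) -> ResiduePartition:
    """Residue partition restricted to intolerant (class A) vs tolerant
    (class B) IDR residues; residues in both kinds of region count as
    intolerant (intolerance dominates), others are excluded."""
    import numpy as np

    overall = {c.region_id: c.overall for c in calls}
    intol = {
        acc: np.zeros(m.size, dtype=bool) for acc, m in partition.masks.items()
    }
    tol = {acc: np.zeros(m.size, dtype=bool) for acc, m in partition.masks.items()}
    for r in regions:
        label = overall.get(r.region_id)
        if label == "intolerant":
            intol[r.accession][r.start - 1 : r.end] = True
        elif label == "tolerant":
            tol[r.accession][r.start - 1 : r.end] = True
    out: dict = {}
    for acc in intol:
        keep = intol[acc] | tol[acc]
        if not keep.any():
            continue
        # restrict to labelled residues; DR mask = intolerant
        out[acc] = intol[acc][keep]
    return ResiduePartition(masks=out)


def run_full(config: RunConfig) -> dict:
    """Run every stage, writing per-stage TSVs and a JSON summary.

    On a stage failure, partial outputs are retained and a MANIFEST notes
    which stages completed before the error is re-raised with its stage
    name.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    completed: list[str] = []
    summary: dict = {"config": dataclasses.asdict(config)}

    def _finish_manifest(status: str) -> None:
        (out_dir / "MANIFEST.json").write_text(
            json.dumps({"status": status, "completed_stages": completed}, indent=2)
        )

    stage = "load_inputs"
    try:
        proteins = am.read_proteins(config.proteins)
        regions = am.read_regions(config.regions, proteins=proteins)
        features, _ = am.read_features(config.features, proteins=proteins)
        variants = am.read_variants(config.variants)
        completed.append(stage)

        stage = "partition"
        partition = am.build_partition(proteins, regions)
        summary["n_DR"] = partition.n_DR
        summary["n_NR"] = partition.n_NR
        completed.append(stage)

        stage = "enrichment_dr_nr"
        results, errors = fe.enrichment_scan(
            partition, features, m=config.bonferroni_m, alpha=config.alpha
        )
        fe.results_to_frame(results).to_csv(
            out_dir / "enrichment_dr_nr.tsv", sep="\t", index=False
        )
        summary["enrichment_dr_nr"] = {
            "n_class_A_enriched": sum(r.call == "class_A_enriched" for r in results),
            "n_class_B_enriched": sum(r.call == "class_B_enriched" for r in results),
            "n_degenerate": len(errors),
        }
        completed.append(stage)

        stage = "burden"
        counts, totals = vb.assign_variants(regions, partition, variants)
        vb.counts_to_frame(regions, counts).to_csv(
            out_dir / "burden.tsv", sep="\t", index=False
        )
        strata = vb.burden_summary(regions, counts)
        assoc = vb.population_association(totals, "all")
        summary["burden"] = {
            "mis_syn_or": assoc.odds_ratio,
            "mis_syn_p": assoc.p,
            "strata": [dataclasses.asdict(s) for s in strata],
        }
        completed.append(stage)

        stage = "intolerance"
        thresholds = (
            it.PUBLISHED_THRESHOLDS
            if config.thresholds == "published"
            else it.compute_thresholds(counts)
        )
        calls = it.classify_all(counts, thresholds, mode=config.intolerance_mode)
        call_summary = it.summarize_calls(calls)
        pd.DataFrame(
            [
                {
                    "region_id": c.region_id,
                    **{v: c.verdicts[v] for v in PROTEIN_CHANGING_TYPES},
                    "overall": c.overall,
                }
                for c in calls
            ]
        ).to_csv(out_dir / "intolerance.tsv", sep="\t", index=False)
        summary["intolerance"] = {
            "thresholds_pathogenic": thresholds.median_pathogenic,
            "thresholds_population": thresholds.median_population,
            "n_intolerant": len(call_summary.intolerant_ids),
            "n_tolerant": len(call_summary.tolerant_ids),
            "n_intolerant_per_type": call_summary.n_intolerant_per_type,
        }
        completed.append(stage)

        stage = "enrichment_intolerant_tolerant"
        it_partition = _intolerant_tolerant_partition(regions, calls, partition)
        if it_partition.n_DR and it_partition.n_NR:
            it_results, it_errors = fe.enrichment_scan(
                it_partition, features, m=config.bonferroni_m, alpha=config.alpha
            )
            fe.results_to_frame(it_results).to_csv(
                out_dir / "enrichment_intolerant_tolerant.tsv", sep="\t", index=False
            )
            summary["enrichment_intolerant_tolerant"] = {
                "n_class_A_enriched": sum(
                    r.call == "class_A_enriched" for r in it_results
                ),
                "n_degenerate": len(it_errors),
            }
        else:
            summary["enrichment_intolerant_tolerant"] = None
        completed.append(stage)

        stage = "importance"
        labels = {c.region_id: c.overall for c in calls}
        if len(set(labels.values()) & {"intolerant", "tolerant"}) == 2:
            X, y, ids = imp.build_matrix(regions, features, labels)
            clf = imp.train_classifier(X, y, seed=config.importance_seed)
            imp_results = imp.permutation_importance(
                clf, X, y, repeats=config.importance_repeats, seed=config.importance_seed
            )
            imp.importance_to_frame(imp_results).to_csv(
                out_dir / "importance.tsv", sep="\t", index=False
            )
            summary["importance"] = {
                "baseline_ap": clf.baseline_ap,
                "top_feature": min(imp_results, key=lambda r: r.rank).feature_class,
                "n_important": sum(r.important for r in imp_results),
            }
        else:
            summary["importance"] = None
        completed.append(stage)
    except Exception as exc:
        _finish_manifest(f"failed at {stage}")
        raise PipelineError(stage, exc) from exc

    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    _finish_manifest("complete")
    return summary
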