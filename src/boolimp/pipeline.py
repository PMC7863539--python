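"""End-to-end workflow and tabular report I/O.

Ties the modules into the standard run: read OTU tables -> log2 transform ->
StepMiner thresholds -> all-pairs Boolean scan -> permutation FDR -> (for
multiple inputs) cross-dataset invariants.  Every statistical default in
:class:`RunConfig` is the published parameter set: noise margin 0.5, S > 3,
error rate < 0.1, 10 permutations for the FDR.

All outputs are plain TSV/JSON so any downstream tool can re-plot them; a
manifest records the config hash, seed, package version and drop counts for
provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .boolean_core import (
    QuadrantCounts,
    RelationKind,
    RelationRecord,
    SignificanceParams,
)
from .discovery import (
    FdrResult,
    InvariantResult,
    RelationTable,
    find_invariants,
    permutation_fdr,
    scan_pairs,
)
from .otu_io import (
    AbundanceMatrix,
    SampleMetadata,
    Scaling,
    align_samples,
    read_metadata,
    read_otu_table,
    transform_log2,
)
from .stepminer import DiscretizationParams, threshold_matrix, write_threshold_report

__all__ = [
    "RunConfig",
    "PipelineError",
    "run_pipeline",
    "export_pair_scatter",
    "write_relation_table",
    "read_relation_table",
    "write_fdr_report",
    "write_invariant_table",
]

log = logging.getLogger("boolimp")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one pipeline run; defaults are the published values."""

    inputs: list[str] = field(default_factory=list)
    metadata: str | None = None
    out_dir: str = "boolimp_out"
    pseudocount: float = 1.0
    scaling: str = "none"
    target_depth: float = 10_000.0
    margin: float = 0.5
    s_min: float = 3.0
    err_max: float = 0.1
    min_side_fraction: float = 0.05
    min_side_count: int = 3
    n_perm: int = 10
    seed: int = 0
    run_fdr: bool = True

    def sig_params(self) -> SignificanceParams:
        return SignificanceParams(
            self.s_min, self.err_max, self.min_side_fraction, self.min_side_count
        )

    def disc_params(self) -> DiscretizationParams:
        return DiscretizationParams(self.margin)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path, "rt", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)


# ---------------------------------------------------------------------------
# report writers / readers


def write_relation_table(rt: RelationTable, path: str | Path) -> None:
    """Relation TSV with '#' metadata header lines so it round-trips."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f"# dataset_id\t{rt.dataset_id}\n")
        fh.write(f"# n_pairs_tested\t{rt.n_pairs_tested}\n")
        fh.write(f"# testable_otus\t{','.join(rt.testable_otus)}\n")
        fh.write(
            "# params\t"
            + json.dumps(
                {**dataclasses.asdict(rt.sig_params), **dataclasses.asdict(rt.disc_params)}
            )
            + "\n"
        )
        cols = ["otu_a", "otu_b", "kind", "a00", "a01", "a10", "a11", "n_used"]
        scols = [f"{p}_{q}" for q in ("q00", "q01", "q10", "q11") for p in ("S", "err")]
        fh.write("\t".join(cols + scols) + "\n")
        for r in rt.records:
            c = r.counts or QuadrantCounts(0, 0, 0, 0)
            stats = {f"{'S'}_{t.quadrant.value}": t.s_statistic for t in r.tests}
            stats |= {f"err_{t.quadrant.value}": t.error_rate for t in r.tests}
            row = [r.otu_a, r.otu_b, r.kind.value, c.a00, c.a01, c.a10, c.a11, c.n_used]
            row += [f"{stats.get(k, float('nan')):.6g}" for k in scols]
            fh.write("\t".join(str(v) for v in row) + "\n")


def read_relation_table(path: str | Path) -> RelationTable:
    meta: dict[str, str] = {}
    rows: list[str] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for ln in fh:
            ln = ln.rstrip("\n")
            if ln.startswith("# "):
                key, _, val = ln[2:].partition("\t")
                meta[key] = val
            elif ln:
                rows.append(ln)
    header = rows[0].split("\t")
    records = []
    for ln in rows[1:]:
        d = dict(zip(header, ln.split("\t")))
        records.append(
            RelationRecord(
                d["otu_a"],
                d["otu_b"],
                RelationKind(d["kind"]),
                QuadrantCounts(int(d["a00"]), int(d["a01"]), int(d["a10"]), int(d["a11"])),
            )
        )
    params = json.loads(meta.get("params", "{}"))
    sig = SignificanceParams(
        params.get("s_min", 3.0),
        params.get("err_max", 0.1),
        params.get("min_side_fraction", 0.05),
        params.get("min_side_count", 3),
    )
    return RelationTable(
        dataset_id=meta.get("dataset_id", str(path)),
        records=records,
        n_pairs_tested=int(meta.get("n_pairs_tested", len(records))),
        testable_otus=[o for o in meta.get("testable_otus", "").split(",") if o],
        sig_params=sig,
        disc_params=DiscretizationParams(params.get("margin", 0.5)),
    )


def write_fdr_report(fdr: FdrResult, path: str | Path, dataset_id: str = "dataset") -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("dataset_id\tn_original\tmean_permuted\tfdr\tn_perm\tseed\tper_permutation\n")
        fdr_s = "NA" if fdr.fdr is None else f"{fdr.fdr:.6g}"
        fh.write(
            f"{dataset_id}\t{fdr.n_original}\t{fdr.mean_permuted:.6g}\t{fdr_s}"
            f"\t{fdr.n_perm}\t{fdr.seed}\t{','.join(map(str, fdr.per_permutation_counts))}\n"
        )


def write_invariant_table(res: InvariantResult, path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f"# datasets\t{','.join(res.dataset_ids)}\n")
        fh.write(f"# n_untestable\t{res.n_untestable}\n")
        fh.write(f"# n_inconsistent\t{res.n_inconsistent}\n")
        fh.write("otu_a\totu_b\tkind\tper_dataset_S_min\tper_dataset_err_max\n")
        for inv in res.invariants:
            s_min, e_max = [], []
            for rec in inv.per_dataset.values():
                best = _best_test(rec)
                if best is not None:
                    s_min.append(best[0])
                    e_max.append(best[1])
            s_str = f"{min(s_min):.4g}" if s_min else "NA"
            e_str = f"{max(e_max):.4g}" if e_max else "NA"
            fh.write(f"{inv.otu_a}\t{inv.otu_b}\t{inv.kind.value}\t{s_str}\t{e_str}\n")


def _best_test(rec: RelationRecord):
    passing = [t for t in rec.tests if t.passes]
    if not passing:
        return None
    return (min(t.s_statistic for t in passing), max(t.error_rate for t in passing))


def export_pair_scatter(
    am: AbundanceMatrix,
    otu_a: str,
    otu_b: str,
    meta: SampleMetadata | None = None,
    factor: str | None = None,
) -> pd.DataFrame:
    """Per-sample (x, y) log2 values of a pair, optionally with a metadata factor.

    This is the data behind an implication scatter plot: OTU A on the x-axis,
    OTU B on the y-axis, one row per sample; rendering is left to the caller.
    """
    x = am.column(otu_a)
    y = am.column(otu_b)
    df = pd.DataFrame({"sample_id": am.sample_ids, "x": x, "y": y})
    if factor is not None:
        if meta is None:
            raise ValueError("a metadata object is required when factor is given")
        fmap = meta.factor(factor)
        df[factor] = [fmap.get(s) for s in am.sample_ids]
    return df


# ---------------------------------------------------------------------------
# pipeline


def _load_abundance(path: str, cfg: RunConfig) -> AbundanceMatrix:
    cm = read_otu_table(path)
    return transform_log2(cm, cfg.pseudocount, Scaling(cfg.scaling), cfg.target_depth)


def run_pipeline(cfg: RunConfig) -> dict[str, object]:
    """Run threshold -> scan -> FDR (-> invariants) and write all reports.

    Returns a manifest dict (also written to ``manifest.json``) mapping
    stages to their artifact paths plus provenance fields.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not cfg.inputs:
        raise PipelineError("otu_io", "no input OTU tables given")
    meta = None
    if cfg.metadata:
        try:
            meta = read_metadata(cfg.metadata)
        except Exception as exc:
            raise PipelineError("otu_io", str(exc)) from exc

    tables: list[RelationTable] = []
    artifacts: dict[str, object] = {}
    drop_counts: dict[str, int] = {}
    for path in cfg.inputs:
        name = Path(path).stem
        try:
            am = _load_abundance(path, cfg)
        except Exception as exc:
            raise PipelineError("otu_io", f"{path}: {exc}") from exc
        if meta is not None:
            try:
                am, _, dropped = align_samples(am, meta)
                drop_counts[name] = len(dropped)
                if dropped:
                    log.info("%s: dropped %d unmatched samples", name, len(dropped))
            except Exception as exc:
                raise PipelineError("otu_io", f"{path}: {exc}") from exc
        try:
            fits, dm = threshold_matrix(am, cfg.disc_params())
        except Exception as exc:
            raise PipelineError("stepminer", f"{path}: {exc}") from exc
        tpath = out / f"{name}.thresholds.tsv"
        write_threshold_report(fits, tpath)
        try:
            rt = scan_pairs(dm, cfg.sig_params(), name, cfg.disc_params())
        except Exception as exc:
            raise PipelineError("boolean_core", f"{path}: {exc}") from exc
        log.info(
            "%s: %d/%d microbes testable, %d pairs tested, %d relationships",
            name, len(rt.testable_otus), am.n_otus, rt.n_pairs_tested, len(rt.records),
        )
        rpath = out / f"{name}.relations.tsv"
        write_relation_table(rt, rpath)
        tables.append(rt)
        artifacts[f"thresholds:{name}"] = str(tpath)
        artifacts[f"relations:{name}"] = str(rpath)
        if cfg.run_fdr:
            try:
                fdr = permutation_fdr(
                    am, cfg.sig_params(), cfg.disc_params(), cfg.n_perm, cfg.seed, rt
                )
            except Exception as exc:
                raise PipelineError("discovery", f"{path}: {exc}") from exc
            fpath = out / f"{name}.fdr.tsv"
            write_fdr_report(fdr, fpath, name)
            artifacts[f"fdr:{name}"] = str(fpath)

    if len(tables) >= 2:
        try:
            inv = find_invariants(tables)
        except Exception as exc:
            raise PipelineError("discovery", str(exc)) from exc
        ipath = out / "invariants.tsv"
        write_invariant_table(inv, ipath)
        artifacts["invariants"] = str(ipath)
        log.info(
            "invariants: %d consistent, %d inconsistent, %d untestable",
            len(inv.invariants), inv.n_inconsistent, inv.n_untestable,
        )

    manifest = {
        "config": dataclasses.asdict(cfg),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "version": __version__,
        "dropped_samples": drop_counts,
        "artifacts": artifacts,
    }
    with open(out / "manifest.json", "wt", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
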