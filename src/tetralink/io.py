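"""Readers, writers, configuration and the end-to-end pipeline.

File contracts (all TSV, bit-stable column orders):

* tetrad count tables: columns ``population, n_y, n_g, n_r, n_b``
  (fluorescent classes in canonical Y, G, R, B order);
* crossover-class count tables: ``population, n1..n5`` (five-class
  order of the crossover-phenotype model);
* three-marker count tables: ``population`` plus the eight haplotype /
  dominant-phenotype columns ``ABC, ABc, AbC, Abc, aBC, aBc, abC, abc``
  (descending lexicographic, coupling parent first);
* genotype matrices: ``marker, chrom, pos, spore1..spore4``;
* crossover calls: BED-like ``chrom, start, end, tetrad, spores,
  status`` with 0-based half-open intervals.

Every pipeline run writes a reproducibility manifest (seed, package
version, config hash) next to its outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .models import CoClassCounts, TetradClassCounts, THREE_LOCUS_CLASSES
from .cocall import CrossoverCall, GenotypeMatrix

__all__ = [
    "AnalysisConfig",
    "read_count_table",
    "read_genotype_matrix",
    "write_genotype_matrix",
    "write_estimates",
    "write_cc_report",
    "write_calls_bed",
    "write_manifest",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

TETRAD_COLS = ["n_y", "n_g", "n_r", "n_b"]
CO_COLS = ["n1", "n2", "n3", "n4", "n5"]
THREE_MARKER_COLS = list(THREE_LOCUS_CLASSES)


@dataclass
class AnalysisConfig:
    """Declarative configuration of one pipeline run."""

    analysis: str  # tetrad-mrf | co-predict | interference | co-call | simulate
    input: Optional[str] = None
    ploidy: str = "disomic"
    min_spacing_bp: int = 10_000
    n_sim: int = 1000
    seed: int = 0
    out_dir: str = "results"
    simulate: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _parse_rows(df: pd.DataFrame, cols: Sequence[str], path) -> list:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    if "population" not in df.columns:
        df = df.copy()
        df.insert(0, "population", [f"pop{i+1}" for i in range(len(df))])
    records = []
    for i, row in df.iterrows():
        vals = [row[c] for c in cols]
        for c, v in zip(cols, vals):
            if pd.isna(v) or v < 0 or int(v) != v:
                raise ValueError(
                    f"{path} row {i + 1}: column {c} must be a non-negative "
                    f"integer, got {v!r}"
                )
        if sum(vals) == 0:
            raise ValueError(f"{path} row {i + 1}: all class counts are zero")
        records.append((str(row["population"]), [int(v) for v in vals]))
    return records


def read_count_table(path, kind: str = "tetrad"):
    """Read a class-count TSV.

    ``kind`` selects the contract: ``tetrad`` -> (population,
    TetradClassCounts), ``co`` -> (population, CoClassCounts),
    ``three-marker`` -> (population, 8-vector in canonical class order).
    """
    df = pd.read_csv(path, sep="\t")
    if kind == "tetrad":
        return [
            (pop, TetradClassCounts.from_sequence(v))
            for pop, v in _parse_rows(df, TETRAD_COLS, path)
        ]
    if kind == "co":
        return [
            (pop, CoClassCounts.from_sequence(v))
            for pop, v in _parse_rows(df, CO_COLS, path)
        ]
    if kind == "three-marker":
        return [
            (pop, np.array(v, dtype=int))
            for pop, v in _parse_rows(df, THREE_MARKER_COLS, path)
        ]
    raise ValueError(f"unknown count-table kind {kind!r}")


def read_genotype_matrix(path, ploidy: str = "disomic") -> GenotypeMatrix:
    """Read one tetrad's genotype matrix (markers x spores TSV)."""
    df = pd.read_csv(path, sep="\t")
    spore_cols = [c for c in df.columns if c.startswith("spore")]
    if len(spore_cols) != 4:
        raise ValueError(f"{path}: expected 4 spore columns, found {spore_cols}")
    for c in ("chrom", "pos"):
        if c not in df.columns:
            raise ValueError(f"{path}: missing column {c}")
    return GenotypeMatrix(
        chrom=str(df["chrom"].iloc[0]),
        positions=df["pos"].to_numpy(),
        dosages=df[spore_cols].to_numpy(),
        ploidy=ploidy,
        marker_ids=[str(m) for m in df.get("marker", df.index)],
    )


def write_genotype_matrix(matrix: GenotypeMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index=False)


def write_estimates(rows: Sequence[dict], path) -> None:
    """Write a Table-1-style estimate table (one row per population)."""
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_cc_report(rows: Sequence[dict], path) -> None:
    """Write a Table-2-style coincidence-coefficient report."""
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_calls_bed(calls: Sequence[CrossoverCall], path) -> None:
    """Write crossover calls as BED-like TSV (0-based, half-open)."""
    df = pd.DataFrame(
        [
            {
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "tetrad": c.tetrad,
                "spores": f"{c.spores[0]}-{c.spores[1]}",
                "status": c.status,
            }
            for c in calls
        ],
        columns=["chrom", "start", "end", "tetrad", "spores", "status"],
    )
    df.to_csv(path, sep="\t", index=False)


def write_manifest(config: AnalysisConfig, out_dir: Path, outputs: Sequence[str]) -> None:
    manifest = {
        "tool": "tetralink",
        "version": __version__,
        "analysis": config.analysis,
        "seed": config.seed,
        "config_hash": config.digest(),
        "config": asdict(config),
        "outputs": sorted(outputs),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Pipeline


def _run_tetrad_mrf(config: AnalysisConfig, out_dir: Path) -> list[str]:
    from . import estimate as est

    rows = []
    for pop, counts in read_count_table(config.input, "tetrad"):
        if config.ploidy == "tetrasomic":
            fit = est.estimate_r_tetrasomic(counts)
            neut = est.neutrality_test(counts, "tetrasomic")
            rows.append(
                {
                    "population": pop,
                    "ploidy": config.ploidy,
                    "n": counts.n,
                    "alpha": fit.alpha.value,
                    "alpha_se": fit.alpha.se,
                    "beta": fit.beta.value,
                    "beta_se": fit.beta.se,
                    "r": fit.r.value,
                    "r_se": fit.r.se,
                    "r_truncated": fit.r.truncated,
                    "neutrality_p": neut.pvalue,
                }
            )
        else:
            fit = est.estimate_r_diploid(counts)
            neut = est.neutrality_test(counts, "disomic")
            rows.append(
                {
                    "population": pop,
                    "ploidy": config.ploidy,
                    "n": counts.n,
                    "r": fit.value,
                    "r_se": fit.se,
                    "r_truncated": fit.truncated,
                    "neutrality_p": neut.pvalue,
                }
            )
    write_estimates(rows, out_dir / "estimates.tsv")
    return ["estimates.tsv"]


def _run_co_predict(config: AnalysisConfig, out_dir: Path) -> list[str]:
    from . import estimate as est

    rows = []
    fits = []
    for pop, counts in read_count_table(config.input, "co"):
        fit = est.estimate_p_co(counts)
        fits.append(fit)
        rows.append(
            {
                "population": pop,
                "n": counts.n,
                "p": fit.p.value,
                "p_se": fit.p.se,
                "alpha": fit.alpha.value,
                "alpha_se": fit.alpha.se,
            }
        )
    total = est.expected_co_per_chromosome([f.p for f in fits])
    rows.append(
        {
            "population": "TOTAL",
            "n": "",
            "p": total.value,
            "p_se": total.se,
            "alpha": "",
            "alpha_se": "",
        }
    )
    write_estimates(rows, out_dir / "co_estimates.tsv")
    return ["co_estimates.tsv"]


def _run_interference(config: AnalysisConfig, out_dir: Path) -> list[str]:
    from . import interference as itf

    rng = np.random.default_rng(config.seed)
    rows = []
    for pop, counts in read_count_table(config.input, "three-marker"):
        n = int(counts.sum())
        if config.ploidy == "tetrasomic":
            cc = itf.cc_from_tetraploid_counts(counts)
        else:
            cc = itf.cc_from_haploid_counts(counts)
        scen = itf.NullScenario(
            ploidy=config.ploidy, n=n, r_ab=cc.r_ab, r_bc=cc.r_bc,
            alpha=0.0 if np.isnan(cc.alpha) else cc.alpha,
        )
        cc = itf.cc_null_test(cc, scen, n_sim=config.n_sim, rng=rng)
        row = {"population": pop, "ploidy": config.ploidy, "n": n}
        row.update({k: v for k, v in cc.coefficients().items()})
        row.update({f"p_{k}": v for k, v in (cc.pvalues or {}).items()})
        row.update({"r_ab": cc.r_ab, "r_bc": cc.r_bc, "n_sim": cc.n_sim})
        rows.append(row)
    write_cc_report(rows, out_dir / "cc_report.tsv")
    return ["cc_report.tsv"]


def _run_co_call(config: AnalysisConfig, out_dir: Path) -> list[str]:
    from . import cocall

    paths = sorted(Path(config.input).glob("*.tsv")) if Path(config.input).is_dir() else [
        Path(config.input)
    ]
    all_calls = []
    calls_by_tetrad = []
    for t, p in enumerate(paths):
        gm = read_genotype_matrix(p, ploidy=config.ploidy)
        gm, retained = cocall.select_markers(gm)
        logger.info("%s: %.1f%% markers retained", p, 100 * retained)
        calls = cocall.call_crossovers(gm, config.min_spacing_bp, tetrad=t)
        calls_by_tetrad.append(calls)
        all_calls.extend(calls)
    write_calls_bed(all_calls, out_dir / "crossovers.bed")
    cocall.summarize_co(calls_by_tetrad).to_csv(
        out_dir / "co_summary.tsv", sep="\t", index=False
    )
    return ["crossovers.bed", "co_summary.tsv"]


def _run_simulate(config: AnalysisConfig, out_dir: Path) -> list[str]:
    from . import simulate as sim
    from .simulate import SimScenario

    scen = SimScenario(seed=config.seed, **config.simulate)
    outputs = []
    if scen.output == "genotype-matrix":
        matrices, truth = sim.make_genotype_matrices(
            scen.ploidy,
            n_tetrads=scen.n,
            n_markers=max(len(scen.r) + 1, 2),
            chrom_length_bp=1_000_000,
            seed=scen.seed,
        )
        for t, gm in enumerate(matrices):
            name = f"tetrad{t}.tsv"
            write_genotype_matrix(gm, out_dir / name)
            outputs.append(name)
        truth.to_csv(out_dir / "truth.bed", sep="\t", index=False)
        outputs.append("truth.bed")
    elif scen.ploidy == "disomic":
        origins, _ = sim.simulate_diploid_tetrads(
            scen.r, scen.n, scen.coincidence, seed=scen.seed
        )
        counts = (
            sim.three_locus_counts_from_spores(origins)
            if origins.shape[-1] == 3
            else sim.tetrad_counts_from_gametes(origins.reshape(-1, origins.shape[-1]))
        )
        _write_counts(counts, out_dir / "class_counts.tsv")
        outputs.append("class_counts.tsv")
    else:
        gametes = sim.simulate_tetraploid_gametes(
            scen.alpha, scen.r, scen.n, scen.coincidence,
            pairing=scen.pairing, seed=scen.seed,
        )
        counts = (
            sim.three_locus_counts_from_spores(gametes)
            if gametes.shape[-1] == 3
            else sim.tetrad_counts_from_gametes(gametes)
        )
        _write_counts(counts, out_dir / "class_counts.tsv")
        outputs.append("class_counts.tsv")
    return outputs


def _write_counts(counts, path) -> None:
    if isinstance(counts, TetradClassCounts):
        df = pd.DataFrame(
            [dict(zip(TETRAD_COLS, counts.as_array().astype(int)))]
        )
    else:
        arr = np.asarray(counts, dtype=int)
        cols = THREE_MARKER_COLS if arr.shape == (8,) else TETRAD_COLS
        df = pd.DataFrame([dict(zip(cols, arr))])
    df.insert(0, "population", "sim")
    df.to_csv(path, sep="\t", index=False)


_RUNNERS = {
    "tetrad-mrf": _run_tetrad_mrf,
    "co-predict": _run_co_predict,
    "interference": _run_interference,
    "co-call": _run_co_call,
    "simulate": _run_simulate,
}


def run_pipeline(config: AnalysisConfig) -> Path:
    """Dispatch one analysis and write its outputs plus a manifest.

    Returns the output directory.  Raises on unknown analysis kinds or
    stage failures (callers map exceptions to exit codes).
    """
    if config.analysis not in _RUNNERS:
        raise ValueError(
            f"unknown analysis kind {config.analysis!r}; "
            f"choose from {sorted(_RUNNERS)}"
        )
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        outputs = _RUNNERS[config.analysis](config, out_dir)
    except Exception:
        logger.exception("pipeline stage %r failed", config.analysis)
        raise
    write_manifest(config, out_dir, outputs)
    return out_dir
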