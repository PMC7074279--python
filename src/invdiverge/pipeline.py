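"""End-to-end orchestration: configuration, stage execution, reporting.

A run takes a :class:`RunConfig`, executes the requested stages in
dependency order (ITS2 species calls -> karyotype statistics -> genomic
divergence), writes every stage table as TSV under the output directory,
and records a JSON manifest (parameters, seeds, input checksums) that
suffices to reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import genome, its2, karyo, simulate

__all__ = ["RunConfig", "PipelineError", "validate_config", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; ``.stage`` names it."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunConfig:
    out_dir: str = "invdiverge_out"
    # stage toggles
    run_its2: bool = True
    run_karyo: bool = True
    run_genome: bool = True
    # inputs (None => synthesise with the simulate module)
    its2_fasta: str | None = None
    its2_reference: str | None = None
    its2_populations: str | None = None  # optional TSV: id <tab> population
    karyotype_table: str | None = None
    vcf: str | None = None
    chromosome_map: str | None = None
    groups_file: str | None = None  # TSV: sample <tab> group
    # override for the synthetic genome panel (a simulate.GenomeSimSpec);
    # ignored when a VCF is supplied
    genome_sim: object | None = None
    # statistical settings (defaults follow the published analysis)
    n_permutations: int = 10_000
    alpha: float = 0.05
    window_bp: int = 5_000
    admixture_restarts: int = 4
    seeds: dict = field(
        default_factory=lambda: {"simulate": 1, "hwe": 2, "fst": 3, "admixture": 4}
    )


def validate_config(config: RunConfig | dict) -> tuple[RunConfig, list[str]]:
    """Normalise a config, filling defaults; every problem is reported at
    once rather than at first failure."""
    if isinstance(config, dict):
        unknown = set(config) - {f for f in RunConfig.__dataclass_fields__}
        cfg = RunConfig(**{k: v for k, v in config.items() if k not in unknown})
        errors = [f"unknown option {k!r}" for k in sorted(unknown)]
    else:
        cfg, errors = config, []
    if cfg.n_permutations < 1:
        errors.append("n_permutations must be positive")
    if not 0 < cfg.alpha < 1:
        errors.append("alpha must be in (0, 1)")
    if cfg.window_bp <= 0:
        errors.append("window_bp must be positive")
    if cfg.admixture_restarts < 1:
        errors.append("admixture_restarts must be positive")
    for stage in ("simulate", "hwe", "fst", "admixture"):
        cfg.seeds.setdefault(stage, 0)
    for name in ("its2_fasta", "its2_reference", "its2_populations",
                 "karyotype_table", "vcf", "chromosome_map", "groups_file"):
        path = getattr(cfg, name)
        if path is not None and not Path(path).exists():
            errors.append(f"{name}: no such file {path!r}")
    return cfg, errors


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_its2(cfg: RunConfig, out: Path, manifest: dict) -> None:
    sim_dir = out / "simulated"
    reference = (
        its2.read_fasta(cfg.its2_reference)[0][1]
        if cfg.its2_reference
        else simulate.synthetic_reference()
    )
    if cfg.its2_fasta:
        records = its2.read_fasta(cfg.its2_fasta)
    else:
        sim_dir.mkdir(parents=True, exist_ok=True)
        spec = simulate.ITS2SimSpec(seed=cfg.seeds["simulate"])
        records, truth = simulate.simulate_its2(spec, reference)
        simulate.write_fasta(records, sim_dir / "its2.fasta")
        truth.to_csv(sim_dir / "its2_truth.tsv", sep="\t", index=False)
    populations = {}
    if cfg.its2_populations:
        df = pd.read_csv(cfg.its2_populations, sep="\t", dtype=str)
        populations = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))

    rows, labelled = [], []
    for rec_id, seq in records:
        pop = populations.get(rec_id, "all")
        try:
            call = its2.classify_sequence(seq, reference)
        except (its2.UnalignableQueryError, its2.UntypeableSpecimenError) as exc:
            rows.append({"id": rec_id, "population": pop, "genotype": "",
                         "label": "untypeable", "note": str(exc)})
            continue
        rows.append(
            {
                "id": rec_id,
                "population": pop,
                "genotype": "".join(call.site_genotype),
                "label": call.label,
                "note": call.confidence_note,
            }
        )
        labelled.append((pop, call.label))
    pd.DataFrame(rows).to_csv(out / "its2_calls.tsv", sep="\t", index=False)
    its2.species_composition(labelled).to_csv(out / "its2_composition.tsv", sep="\t")
    manifest["its2"] = {"n_records": len(records)}


def _stage_karyo(cfg: RunConfig, out: Path, manifest: dict) -> None:
    sim_dir = out / "simulated"
    if cfg.karyotype_table:
        records = karyo.read_karyotype_table(cfg.karyotype_table)
    else:
        sim_dir.mkdir(parents=True, exist_ok=True)
        spec = simulate.KaryoSimSpec(
            groups=simulate.DEFAULT_KARYO_GROUPS, seed=cfg.seeds["simulate"]
        )
        records = simulate.simulate_karyotypes(spec)
        karyo.write_karyotype_table(records, sim_dir / "karyotypes.tsv")
    groups = karyo.group_records(records)

    hwe_rows = []
    for (pop, sp), recs in sorted(groups.items()):
        for arm in karyo.ARMS:
            try:
                res = karyo.hwe_permutation_test(
                    recs, arm, n_perm=cfg.n_permutations, seed=cfg.seeds["hwe"]
                )
            except ValueError as exc:
                hwe_rows.append({"population": pop, "species": sp, "locus": arm,
                                 "status": f"skipped ({exc})"})
                continue
            hwe_rows.append(
                {
                    "population": pop,
                    "species": sp,
                    "locus": arm,
                    "status": res.status,
                    "fis": res.fis,
                    "p_value": res.p_value,
                }
            )
    hwe_df = pd.DataFrame(hwe_rows)
    hwe_df["significant_after_bonferroni"] = pd.Series(pd.NA, dtype="boolean")
    tested = hwe_df["status"] == "tested"
    if tested.any():
        flags = karyo.bonferroni_adjust(hwe_df.loc[tested, "p_value"], cfg.alpha)
        hwe_df.loc[tested, "significant_after_bonferroni"] = flags
    hwe_df.to_csv(out / "karyo_hwe.tsv", sep="\t", index=False)

    keys = sorted(groups)
    fst_rows = []
    for i, ka in enumerate(keys):
        for kb in keys[i + 1 :]:
            res = karyo.pairwise_fst(
                groups[ka],
                groups[kb],
                n_perm=cfg.n_permutations,
                seed=cfg.seeds["fst"],
                labels=(", ".join(ka), ", ".join(kb)),
            )
            fst_rows.append(
                {"sample_a": res.pair[0], "sample_b": res.pair[1],
                 "theta": res.theta, "p_value": res.p_value}
            )
    fst_df = pd.DataFrame(fst_rows)
    if len(fst_df):
        fst_df["significant_after_bonferroni"] = karyo.bonferroni_adjust(
            fst_df["p_value"], cfg.alpha
        )
    fst_df.to_csv(out / "karyo_pairwise_fst.tsv", sep="\t", index=False)

    karyo.arrangement_summary(records).to_csv(
        out / "karyo_arrangements.tsv", sep="\t", index=False
    )
    freq = karyo.inverted_frequency_matrix(records)
    freq.to_csv(out / "karyo_inverted_freqs.tsv", sep="\t")
    pca = karyo.inversion_frequency_pca(freq)
    pca.scores.to_csv(out / "karyo_pca_scores.tsv", sep="\t")
    pd.DataFrame(
        {"component": pca.scores.columns, "percent_variance": pca.percent_variance}
    ).to_csv(out / "karyo_pca_variance.tsv", sep="\t", index=False)
    manifest["karyo"] = {"n_records": len(records), "n_groups": len(groups)}


def _stage_genome(cfg: RunConfig, out: Path, manifest: dict) -> None:
    sim_dir = out / "simulated"
    if cfg.vcf:
        samples, raw = genome.read_vcf(cfg.vcf)
        if cfg.chromosome_map is None:
            raise PipelineError("genome", "chromosome_map required with an input VCF")
        cmap = genome.read_chromosome_map(cfg.chromosome_map)
        if cfg.groups_file is None:
            raise PipelineError("genome", "groups_file required with an input VCF")
        gdf = pd.read_csv(cfg.groups_file, sep="\t", dtype=str)
        by_group = gdf.groupby(gdf.columns[1])[gdf.columns[0]].apply(list)
        if len(by_group) != 2:
            raise PipelineError("genome", "groups_file must define exactly two groups")
        group_a, group_b = (by_group.iloc[0], by_group.iloc[1])
    else:
        sim_dir.mkdir(parents=True, exist_ok=True)
        spec = cfg.genome_sim or simulate.GenomeSimSpec(seed=cfg.seeds["simulate"])
        samples, raw, cmap, truth = simulate.simulate_genotypes(spec)
        simulate.write_vcf(samples, raw, sim_dir / "genotypes.vcf")
        simulate.write_chromosome_map(cmap, sim_dir / "chromosome_map.tsv")
        truth.to_csv(sim_dir / "genome_truth.tsv", sep="\t", index=False)
        group_a = [s for s in samples if s.startswith("mes")]
        group_b = [s for s in samples if s.startswith("dac")]

    kept = genome.filter_variants(raw)
    placed, unplaced = genome.lift_records(kept, cmap)
    windows = genome.windowed_fst(placed, samples, group_a, group_b, cfg.window_bp)
    genome.windows_to_frame(windows).to_csv(out / "fst_windows.tsv", sep="\t", index=False)

    chroms = sorted({w.chromosome for w in windows})
    mean_rows = []
    for chrom in chroms:
        for weighting in ("mean_of_windows", "ratio_of_sums"):
            mean_rows.append(
                {
                    "scope": chrom,
                    "weighting": weighting,
                    "mean_fst": genome.mean_fst(windows, {chrom}, weighting=weighting),
                }
            )
    pd.DataFrame(mean_rows).to_csv(out / "fst_means.tsv", sep="\t", index=False)

    autosomal = [r for r in placed if r.contig != "X"]
    G = genome.genotype_matrix(autosomal)
    anc = genome.admixture_em(
        G, K=2, seed=cfg.seeds["admixture"], n_restarts=cfg.admixture_restarts
    )
    pd.DataFrame(
        {"sample": samples, "q1": anc.q[:, 0], "q2": anc.q[:, 1]}
    ).to_csv(out / "admixture_q.tsv", sep="\t", index=False)

    pca = genome.genotype_pca(G)
    scores = pd.DataFrame(
        pca.scores,
        index=samples,
        columns=[f"PC{i+1}" for i in range(pca.scores.shape[1])],
    )
    scores.to_csv(out / "genotype_pca_scores.tsv", sep="\t")
    manifest["genome"] = {
        "n_raw_snvs": len(raw),
        "n_filtered_snvs": len(kept),
        "n_unplaced": len(unplaced),
        "n_windows": len(windows),
        "admixture_converged": bool(anc.converged),
    }


def run_pipeline(config: RunConfig | dict) -> dict:
    """Execute the configured stages; returns the manifest dict.

    On any stage failure a FAILED marker naming the stage is written next
    to the partial outputs and :class:`PipelineError` is raised.
    """
    cfg, errors = validate_config(config)
    if errors:
        raise PipelineError("config", "; ".join(errors))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": {
            "n_permutations": cfg.n_permutations,
            "alpha": cfg.alpha,
            "window_bp": cfg.window_bp,
            "seeds": dict(cfg.seeds),
        },
        "inputs": {},
        "stages": [],
    }
    for name in ("its2_fasta", "its2_reference", "karyotype_table", "vcf",
                 "chromosome_map", "groups_file"):
        path = getattr(cfg, name)
        if path:
            manifest["inputs"][name] = {"path": str(path), "sha256": _sha256(Path(path))}

    stages = [
        ("its2", cfg.run_its2, _stage_its2),
        ("karyo", cfg.run_karyo, _stage_karyo),
        ("genome", cfg.run_genome, _stage_genome),
    ]
    for name, enabled, fn in stages:
        if not enabled:
            continue
        t0 = time.perf_counter()
        try:
            fn(cfg, out, manifest)
        except PipelineError:
            (out / "FAILED").write_text(f"stage {name} failed\n")
            raise
        except Exception as exc:
            (out / "FAILED").write_text(f"stage {name} failed: {exc}\n")
            raise PipelineError(name, str(exc)) from exc
        manifest["stages"].append({"stage": name, "seconds": round(time.perf_counter() - t0, 3)})
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    summary = [f"invdiverge run summary ({time.strftime('%Y-%m-%d %H:%M:%S')})"]
    for s in manifest["stages"]:
        summary.append(f"  stage {s['stage']}: ok ({s['seconds']} s)")
    (out / "summary.txt").write_text("\n".join(summary) + "\n")
    return manifest
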