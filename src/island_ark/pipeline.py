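"""Configuration-driven orchestration of the analysis stages.

A YAML run configuration enables any subset of the stages (synthetic-data
generation, sequence statistics, microsatellite statistics, ABC fitting,
morphometrics); :func:`run_pipeline` executes them in dependency order,
writes every artifact under the output directory, and returns a manifest
listing each artifact with its SHA-256 checksum.  Every stochastic stage
must carry an explicit seed — the configuration is rejected otherwise — and
the configuration itself is copied verbatim into the output directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import abc_infer, morpho, msatstats, seqstats, synthdata
from .io_formats import read_fasta, read_genotypes, read_tps

log = logging.getLogger(__name__)

STAGES = ("synth", "seqstats", "msatstats", "abc", "morpho")
_STOCHASTIC = {"synth", "abc"}

_KNOWN_KEYS: dict[str, set[str]] = {
    "": {"output_dir", "stages"},
    "synth": {"enabled", "kind", "seed", "params"},
    "seqstats": {"enabled", "fasta", "pop", "boot", "seed", "policy"},
    "msatstats": {"enabled", "genotypes", "format", "fst", "hwe", "seed",
                  "permutations"},
    "abc": {"enabled", "genotypes", "format", "source", "targets", "draws",
            "tolerance", "seed", "mu_msat"},
    "morpho": {"enabled", "tps", "slide", "groups"},
}


class PipelineError(RuntimeError):
    """A stage failed; carries the partial manifest."""

    def __init__(self, msg: str, manifest: dict):
        super().__init__(msg)
        self.manifest = manifest


@dataclass
class RunConfig:
    """Validated run configuration."""
    output_dir: Path
    stages: dict[str, dict] = field(default_factory=dict)
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        issues = validate_config_dict(raw)
        if issues:
            raise ValueError("invalid configuration:\n  " + "\n  ".join(issues))
        return cls(output_dir=Path(raw.get("output_dir", "island-ark-out")),
                   stages=raw.get("stages", {}), raw=raw)


def validate_config(path: str | Path) -> list[str]:
    """Validation report for a configuration file (empty = valid)."""
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        return [f"YAML parse failure: {exc}"]
    return validate_config_dict(raw)


def validate_config_dict(raw) -> list[str]:
    issues: list[str] = []
    if not isinstance(raw, dict):
        return ["configuration must be a mapping"]
    for key in raw:
        if key not in _KNOWN_KEYS[""]:
            issues.append(f"unknown top-level key {key!r}")
    stages = raw.get("stages", {})
    if not isinstance(stages, dict):
        return issues + ["'stages' must be a mapping"]
    for name, cfg in stages.items():
        if name not in STAGES:
            issues.append(f"unknown stage {name!r}")
            continue
        if not isinstance(cfg, dict):
            issues.append(f"stages.{name} must be a mapping")
            continue
        for key in cfg:
            if key not in _KNOWN_KEYS[name]:
                issues.append(f"unknown key stages.{name}.{key}")
        if cfg.get("enabled"):
            if name in _STOCHASTIC and "seed" not in cfg:
                issues.append(f"stages.{name}: enabled stochastic stage "
                              "needs an explicit seed")
            if name == "seqstats" and cfg.get("boot") and "seed" not in cfg:
                issues.append("stages.seqstats: bootstrap needs a seed")
            if name == "msatstats" and (cfg.get("hwe")
                                        or cfg.get("permutations")) \
                    and "seed" not in cfg:
                issues.append("stages.msatstats: hwe/permutations need a seed")
            tol = cfg.get("tolerance")
            if tol is not None and not (0 < tol <= 1):
                issues.append(f"stages.abc.tolerance={tol} outside (0, 1]")
    return issues


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig | str | Path) -> dict:
    """Execute the enabled stages; return (and write) the output manifest."""
    if not isinstance(config, RunConfig):
        config = RunConfig.from_file(config)
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(config.raw))
    manifest: dict = {"artifacts": [], "stages": {}}

    def record(path: Path) -> None:
        manifest["artifacts"].append({
            "path": str(path), "sha256": _checksum(path),
            "bytes": path.stat().st_size})

    record(out / "config.yaml")
    synth_paths: dict[str, str] = {}
    try:
        for name in STAGES:
            cfg = config.stages.get(name, {})
            if not cfg.get("enabled"):
                continue
            t0 = time.time()
            log.info("stage %s starting (seed=%s)", name, cfg.get("seed"))
            if name == "synth":
                kind = cfg.get("kind", "colonization")
                params = cfg.get("params", {}) or {}
                gen = {"colonization": synthdata.synth_colonization,
                       "expansion": synthdata.synth_expansion_alignment,
                       "landmarks": synthdata.synth_landmarks}[kind]
                study = gen(seed=int(cfg["seed"]), **params)
                paths = study.write(out / "synth")
                synth_paths[kind] = paths["data"]
                for p in paths.values():
                    record(Path(p))
            elif name == "seqstats":
                fasta = cfg.get("fasta") or synth_paths.get("expansion")
                aln = read_fasta(fasta)
                if cfg.get("pop"):
                    aln = aln.subset(cfg["pop"])
                stats = seqstats.diversity(aln)
                obs = seqstats.mismatch_distribution(aln)
                fit = seqstats.fit_sudden_expansion(obs, aln.n)
                row = {
                    "n": stats.n, "S": stats.S, "h": stats.h,
                    "h_sd": stats.h_sd, "pi": stats.pi, "pi_sd": stats.pi_sd,
                    "tajimas_d": seqstats.tajimas_d(aln),
                    "fus_fs": seqstats.fus_fs(aln),
                    "rozas_r2": seqstats.rozas_r2(aln),
                    "mismatch_tau": fit.tau, "mismatch_ssd": fit.ssd,
                }
                boot = int(cfg.get("boot", 0))
                if boot:
                    row["p_ssd"] = seqstats.ssd_pvalue(
                        fit, aln.n, n_boot=boot, seed=int(cfg["seed"]))
                p = out / "seqstats.tsv"
                p.write_text("\t".join(row) + "\n" +
                             "\t".join(f"{v:.6g}" if isinstance(v, float)
                                       else str(v) for v in row.values())
                             + "\n")
                record(p)
            elif name == "msatstats":
                gpath = cfg.get("genotypes") or synth_paths.get("colonization")
                table = read_genotypes(gpath, cfg.get("format", "genepop"))
                df = msatstats.summarize_table(table)
                p = out / "msatstats.tsv"
                df.to_csv(p, sep="\t", index=False)
                record(p)
                if cfg.get("fst"):
                    fm = msatstats.fst(
                        table, permutations=int(cfg.get("permutations", 0)),
                        seed=cfg.get("seed"))
                    p2 = out / "fst.json"
                    p2.write_text(json.dumps({
                        "labels": fm.labels, "overall": fm.overall,
                        "p_overall": None if np.isnan(fm.p_overall)
                        else fm.p_overall,
                        "pairwise": fm.values.tolist()}, indent=1))
                    record(p2)
            elif name == "abc":
                gpath = cfg.get("genotypes") or synth_paths.get("colonization")
                table = read_genotypes(gpath, cfg.get("format", "genepop"))
                source = cfg.get("source") or "source"
                targets = cfg.get("targets") or \
                    [p for p in table.populations if p != source][:1]
                target = targets[0]
                priors = abc_infer.default_priors()
                obs = abc_infer.compute_summaries(table, source, [target])
                n_t = int(table.pop_mask(target).sum())
                n_s = int(table.pop_mask(source).sum())
                draws, sims, _names = abc_infer.simulate_reference(
                    priors, n_t, n_s, len(table.loci),
                    int(cfg.get("draws", 1000)), int(cfg["seed"]),
                    mu_msat=float(cfg.get("mu_msat", 2e-4)))
                res = abc_infer.abc_fit(obs, draws, sims,
                                        float(cfg.get("tolerance", 0.05)),
                                        seed=int(cfg["seed"]))
                p = out / "abc.json"
                p.write_text(json.dumps({
                    "modes": res.modes, "tolerance": res.tolerance,
                    "n_retained": int(len(res.retained)),
                    "T_col_ci95": res.credible_interval("T_col")},
                    indent=1))
                record(p)
            elif name == "morpho":
                tps = cfg.get("tps") or synth_paths.get("landmarks")
                ds = read_tps(tps)
                if cfg.get("groups"):
                    for ln in Path(cfg["groups"]).read_text().splitlines()[1:]:
                        s, g = ln.split("\t")
                        ds.groups[s] = g
                fit = morpho.gpa_with_sliding(ds) if cfg.get("slide") \
                    else morpho.gpa(ds)
                pca = morpho.shape_pca(fit)
                p = out / "pca_scores.tsv"
                with p.open("w") as fh:
                    ncomp = min(5, pca.scores.shape[1])
                    fh.write("specimen\tlog_centroid_size\t" +
                             "\t".join(f"PC{i + 1}" for i in range(ncomp))
                             + "\n")
                    for i, s in enumerate(fit.specimens):
                        fh.write(s + "\t"
                                 + f"{np.log(fit.centroid_sizes[i]):.6g}\t"
                                 + "\t".join(f"{pca.scores[i, j]:.6g}"
                                             for j in range(ncomp)) + "\n")
                record(p)
                p2 = out / "variance_explained.tsv"
                p2.write_text("\n".join(
                    f"PC{i + 1}\t{v:.6g}" for i, v in
                    enumerate(pca.variance_explained)) + "\n")
                record(p2)
            manifest["stages"][name] = {
                "seconds": round(time.time() - t0, 3),
                "seed": cfg.get("seed")}
    except Exception as exc:
        mp = out / "manifest.json"
        mp.write_text(json.dumps(manifest, indent=1))
        raise PipelineError(f"stage failed: {exc}", manifest) from exc
    mp = out / "manifest.json"
    mp.write_text(json.dumps(manifest, indent=1))
    return manifest
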