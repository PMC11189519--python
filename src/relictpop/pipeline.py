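"""End-to-end workflow orchestration with a reproducibility manifest.

Stages (each also available standalone through the CLI):

1. ``simulate``  - synthesize an all-sites cohort VCF (skipped when an
   input VCF is supplied)
2. ``combine``   - split all-sites records into invariant and variable
   parts, apply the depth/SNP filter cascade to each, and concatenate
3. ``structure`` - genic extraction, full-call filter, LD pruning, PCA,
   IBS distances, NJ tree (rooted when an outgroup group is present)
4. ``diversity`` - per-group windowed pi plus pairwise dxy/Fst tables
5. ``ld``        - group LD decay curves (with optional downsampling)
6. ``neutrality``- folded SFS and sliding-window Tajima's D for one group
7. ``novel``     - novel-allele flags and the exact-subset overlap table

The manifest records parameter snapshots and SHA-256 checksums of every
stage input and output; re-running with unchanged inputs skips stages whose
outputs are already present and consistent.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from relictpop import __version__, diversity, linkage, neutrality, novel_alleles, structure
from relictpop.simpop import (
    FULL_COHORT_SAMPLES,
    contig_lengths,
    draw_diploids,
    emit_cohort_vcf,
    preset_scenario,
    simulate_wf,
)
from relictpop.variant_store import (
    CohortMatrix,
    FilterParams,
    concat_sites,
    filter_sites,
    intersect_genic,
    read_bed,
    read_groups,
    read_vcf,
    split_sites,
    write_vcf,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "combine", "structure", "diversity", "ld", "neutrality", "novel")


@dataclass
class RunConfig:
    """Flat key-value run configuration with cohort-style defaults."""

    out_dir: Path
    vcf: Path | None = None
    groups: Path | None = None
    bed: Path | None = None
    stages: tuple[str, ...] = STAGES
    seed: int = 42
    # simulate
    preset: str = "full_cohort"
    length_bp: int = 60_000
    missing_rate: float = 0.0
    depth_mean: float = 30.0
    # filters
    max_missing_count: int = 0
    max_alleles: int = 2
    min_mac: int = 1
    min_maf: float = 0.05
    min_mean_depth: float = 10.0
    max_mean_depth: float = 100.0
    # analysis parameters
    window_bp: int = 10_000
    ld_max_dist: int = 500_000
    ld_downsample: int = 10
    ld_reps: int = 10
    prune_window: int = 50
    prune_step: int = 10
    prune_r2: float = 0.1
    pca_components: int = 20
    taj_window_bp: int = 50_000
    taj_step_bp: int = 10_000
    focal_group: str = "MK"
    outgroup_label: str = "outgroup"
    reference_groups: tuple[str, ...] = ("wild", "outgroup")
    focal_groups: tuple[str, ...] = ("MK", "LR1", "LR2", "cultivar")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        kv: dict[str, str] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}, line {lineno}: expected key=value")
            key, value = line.split("=", 1)
            kv[key.strip()] = value.strip()
        return cls.from_mapping(kv)

    @classmethod
    def from_mapping(cls, kv: dict[str, str]) -> "RunConfig":
        if "out_dir" not in kv:
            raise ValueError("config must set out_dir")
        kwargs: dict = {"out_dir": Path(kv.pop("out_dir"))}
        paths = {"vcf", "groups", "bed"}
        tuples = {"stages", "reference_groups", "focal_groups"}
        for key, value in kv.items():
            if not hasattr(cls, "__dataclass_fields__") or key not in cls.__dataclass_fields__:
                raise ValueError(f"unknown config key {key!r}")
            if key in paths:
                kwargs[key] = Path(value)
            elif key in tuples:
                kwargs[key] = tuple(x.strip() for x in value.split(",") if x.strip())
            else:
                current = cls.__dataclass_fields__[key].default
                caster = type(current) if current is not None else str
                kwargs[key] = caster(value)
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for p in (self.vcf, self.groups, self.bed):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        if self.vcf is None and "simulate" not in self.stages:
            raise ValueError("either supply vcf= or enable the simulate stage")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    version: str
    config: dict
    stages: dict[str, dict] = field(default_factory=dict)

    def save(self, path: Path) -> None:
        path.write_text(json.dumps({"version": self.version, "config": self.config,
                                    "stages": self.stages}, indent=2, default=str))

    @classmethod
    def load(cls, path: Path) -> "RunManifest":
        raw = json.loads(path.read_text())
        return cls(version=raw["version"], config=raw["config"], stages=raw["stages"])


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the enabled stages in dependency order.

    Deterministic for a fixed config and inputs; stages whose outputs exist
    and whose input checksums match the on-disk manifest are skipped.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    previous = RunManifest.load(manifest_path) if manifest_path.exists() else None
    manifest = RunManifest(version=__version__, config={
        k: v for k, v in config.__dict__.items()
    })

    runner = _StageRunner(config, out, previous, manifest)
    for stage in STAGES:
        if stage not in config.stages:
            continue
        if stage == "simulate" and config.vcf is not None:
            continue
        try:
            runner.run(stage)
        except Exception as exc:  # noqa: BLE001 - name the failing stage
            raise PipelineError(stage, exc) from exc
    manifest.save(manifest_path)
    return manifest


class _StageRunner:
    def __init__(self, config: RunConfig, out: Path, previous: RunManifest | None,
                 manifest: RunManifest):
        self.cfg = config
        self.out = out
        self.previous = previous
        self.manifest = manifest
        self._cache: dict[str, CohortMatrix] = {}

    # -- plumbing ----------------------------------------------------------
    def run(self, stage: str) -> None:
        inputs, outputs, fn = getattr(self, f"_stage_{stage}")()
        in_shas = {str(p): _sha256(Path(p)) for p in inputs if Path(p).exists()}
        if self._can_skip(stage, in_shas, outputs):
            logger.info("stage %s: outputs up to date, skipped", stage)
            self.manifest.stages[stage] = self.previous.stages[stage]
            return
        t0 = time.time()
        fn()
        self.manifest.stages[stage] = {
            "inputs": in_shas,
            "outputs": {str(p): _sha256(Path(p)) for p in outputs},
            "seconds": round(time.time() - t0, 3),
        }
        logger.info("stage %s: done in %.1fs", stage, time.time() - t0)

    def _can_skip(self, stage: str, in_shas: dict, outputs: list[Path]) -> bool:
        if self.previous is None or stage not in self.previous.stages:
            return False
        prev = self.previous.stages[stage]
        if prev.get("inputs") != in_shas:
            return False
        for p in outputs:
            if not Path(p).exists():
                return False
            if prev.get("outputs", {}).get(str(p)) != _sha256(Path(p)):
                return False
        return True

    # -- shared data -------------------------------------------------------
    @property
    def raw_vcf(self) -> Path:
        return Path(self.cfg.vcf) if self.cfg.vcf else self.out / "cohort.vcf"

    @property
    def groups_path(self) -> Path:
        return Path(self.cfg.groups) if self.cfg.groups else self.out / "groups.tsv"

    @property
    def combined_vcf(self) -> Path:
        return self.out / "combined.vcf"

    def _load(self, path: Path) -> CohortMatrix:
        key = str(path)
        if key not in self._cache:
            m = read_vcf(path)
            m.groups = read_groups(self.groups_path)
            self._cache[key] = m
        return self._cache[key]

    # -- stage definitions -------------------------------------------------
    def _stage_simulate(self):
        cfg = self.cfg
        outputs = [self.raw_vcf, self.groups_path]

        def fn():
            model = preset_scenario(cfg.preset)
            samples = dict(FULL_COHORT_SAMPLES) if cfg.preset == "full_cohort" else None
            if samples is None:
                samples = {p.name: min(10, p.ne_at(0)) for p in model.populations}
            res = simulate_wf(model, cfg.length_bp, samples, seed=cfg.seed)
            m = draw_diploids(res, pairing_seed=cfg.seed + 1,
                              missing_rate=cfg.missing_rate, depth_mean=cfg.depth_mean)
            emit_cohort_vcf(m, self.raw_vcf, contigs=contig_lengths(res),
                            groups_path=self.groups_path)
            logger.info("simulate: %d samples x %d sites", m.n_samples, m.n_sites)

        return [], outputs, fn

    def _filter_params(self, with_maf: bool = True) -> FilterParams:
        cfg = self.cfg
        return FilterParams(
            max_missing_count=cfg.max_missing_count,
            max_alleles=cfg.max_alleles,
            min_mac=cfg.min_mac,
            min_maf=cfg.min_maf if with_maf else 0.0,
            min_mean_depth=cfg.min_mean_depth,
            max_mean_depth=cfg.max_mean_depth,
            drop_indels=True,
        )

    def _stage_combine(self):
        outputs = [self.combined_vcf]

        def fn():
            m = self._load(self.raw_vcf)
            invariant, variable = split_sites(m)
            n = m.n_samples
            snp_kept = filter_sites(variable, self._filter_params(with_maf=True))
            inv_params = FilterParams(
                max_missing_count=n, max_alleles=2**31, min_mac=0, min_maf=0.0,
                min_mean_depth=self.cfg.min_mean_depth,
                max_mean_depth=self.cfg.max_mean_depth, drop_indels=True,
            )
            inv_kept = filter_sites(invariant, inv_params)
            combined = concat_sites(inv_kept, snp_kept)
            write_vcf(combined, self.combined_vcf)
            logger.info(
                "combine: %d sites in -> %d invariant + %d SNP -> %d combined",
                m.n_sites, inv_kept.n_sites, snp_kept.n_sites, combined.n_sites,
            )

        return [self.raw_vcf, self.groups_path], outputs, fn

    def _stage_structure(self):
        cfg = self.cfg
        coords = self.out / "pca_coords.tsv"
        tree_path = self.out / "nj_tree.nwk"
        dist_path = self.out / "ibs_distance.tsv"
        kept_ids = self.out / "pruned_kept_ids.txt"

        def fn():
            m = self._load(self.combined_vcf)
            _, variable = split_sites(m)
            if cfg.bed is not None:
                variable = intersect_genic(variable, read_bed(cfg.bed))
            full = variable.take_sites((variable.dosages >= 0).all(axis=0))
            pruned, kept, _removed = linkage.ld_prune(
                full, window_snps=cfg.prune_window, step_snps=cfg.prune_step,
                r2_max=cfg.prune_r2,
            )
            kept_ids.write_text(
                "".join(f"{s.site_id or f'{s.chrom}_{s.pos}'}\n" for s in pruned.sites)
            )
            res = structure.pca(pruned, n_components=cfg.pca_components)
            header = "sample\t" + "\t".join(
                f"PC{i + 1}({p:.1f}%)" for i, p in enumerate(res.pct_variance)
            )
            with open(coords, "w") as fh:
                fh.write(header + "\n")
                for i, s in enumerate(res.samples):
                    fh.write(s + "\t" + "\t".join(f"{x:.6g}" for x in res.coordinates[i]) + "\n")
            dist = structure.ibs_distance(pruned)
            pd.DataFrame(dist.values, index=dist.labels, columns=dist.labels).to_csv(
                dist_path, sep="\t"
            )
            tree = structure.nj_tree(dist)
            if m.groups is not None and cfg.outgroup_label in m.groups.labels():
                out_labels = m.groups.members(cfg.outgroup_label)
                tree = structure.root_with_outgroup(tree, out_labels)
            structure.write_newick(tree, str(tree_path))
            logger.info("structure: %d genic SNPs -> %d after pruning", full.n_sites,
                        pruned.n_sites)

        return [self.combined_vcf, self.groups_path], [coords, tree_path, dist_path, kept_ids], fn

    def _stage_diversity(self):
        cfg = self.cfg
        pi_path = self.out / "pi_windows.tsv"
        pair_path = self.out / "dxy_fst_windows.tsv"
        het_path = self.out / "het_fis.tsv"

        def fn():
            m = self._load(self.combined_vcf)
            labels = [g for g in m.groups.labels() if g != cfg.outgroup_label]
            frames = []
            for g in labels:
                df = diversity.windows_to_frame(diversity.pi_windows(m, g, cfg.window_bp))
                df.insert(0, "group", g)
                frames.append(df)
            pd.concat(frames).to_csv(pi_path, sep="\t", index=False)
            pair_frames = []
            focal = cfg.focal_group
            for g in labels:
                if g == focal:
                    continue
                for stat, wins in (
                    ("dxy", diversity.dxy_windows(m, focal, g, cfg.window_bp)),
                    ("fst", diversity.fst_windows(m, focal, g, cfg.window_bp)),
                ):
                    df = diversity.windows_to_frame(wins)
                    df.insert(0, "pair", f"{focal}~{g}")
                    pair_frames.append(df)
            pd.concat(pair_frames).to_csv(pair_path, sep="\t", index=False)
            _, variable = split_sites(m)
            reports = diversity.het_fis(variable)
            with open(het_path, "w") as fh:
                fh.write("sample\tgroup\tobs_hom\texp_hom\tn_called\the\tfis\n")
                for r in reports:
                    grp = m.groups.label_of(r.sample) if r.sample in m.groups else "NA"
                    fh.write(
                        f"{r.sample}\t{grp}\t{r.obs_hom}\t{r.exp_hom:.3f}\t"
                        f"{r.n_called}\t{r.he:.6g}\t{r.fis:.6g}\n"
                    )

        return [self.combined_vcf, self.groups_path], [pi_path, pair_path, het_path], fn

    def _stage_ld(self):
        cfg = self.cfg
        decay_path = self.out / "ld_decay.tsv"

        def fn():
            m = self._load(self.combined_vcf)
            _, variable = split_sites(m)
            rows = []
            for g in m.groups.labels():
                if g == cfg.outgroup_label:
                    continue
                members = m.groups.members(g)
                if len(members) > cfg.ld_downsample:
                    curves = linkage.downsampled_decay(
                        variable, g, n_sub=cfg.ld_downsample, reps=cfg.ld_reps,
                        seed=cfg.seed, max_dist=cfg.ld_max_dist,
                    )
                else:
                    pairs = linkage.pairwise_r2(variable, g, max_dist=cfg.ld_max_dist)
                    curves = [linkage.decay_curve(pairs)] if pairs else []
                for rep, c in enumerate(curves):
                    for left, mean, count in zip(c.bin_left, c.mean_r2, c.count):
                        if count:
                            rows.append((g, rep, int(left), float(mean), int(count)))
            pd.DataFrame(rows, columns=["group", "rep", "dist_bin", "mean_r2", "n_pairs"]).to_csv(
                decay_path, sep="\t", index=False
            )

        return [self.combined_vcf, self.groups_path], [decay_path], fn

    def _stage_neutrality(self):
        cfg = self.cfg
        taj_path = self.out / "tajima_windows.tsv"
        sfs_path = self.out / "folded_sfs.tsv"

        def fn():
            m = self._load(self.combined_vcf)
            wins = neutrality.tajima_windows(m, cfg.focal_group, cfg.taj_window_bp,
                                             cfg.taj_step_bp)
            with open(taj_path, "w") as fh:
                fh.write("chrom\tstart\tend\tn_sites\tS\ttheta_pi\ttheta_w\ttajima_d\n")
                for w in wins:
                    fh.write(
                        f"{w.chrom}\t{w.start}\t{w.end}\t{w.n_sites}\t{w.s}\t"
                        f"{w.theta_pi:.6g}\t{w.theta_w:.6g}\t{w.tajima_d:.6g}\n"
                    )
            sfs = neutrality.folded_sfs(m, cfg.focal_group)
            with open(sfs_path, "w") as fh:
                fh.write("minor_count\tn_sites\n")
                for i, c in enumerate(sfs.bins):
                    fh.write(f"{i}\t{int(c)}\n")

        return [self.combined_vcf, self.groups_path], [taj_path, sfs_path], fn

    def _stage_novel(self):
        cfg = self.cfg
        flags_path = self.out / "novel_flags.tsv"
        counts_path = self.out / "novel_overlap.tsv"

        def fn():
            m = self._load(self.combined_vcf)
            labels = set(m.groups.labels())
            if not set(cfg.reference_groups) <= labels:
                logger.warning("novel stage skipped: reference groups absent")
                flags_path.write_text("site_id\n")
                counts_path.write_text("subset\tcount\n")
                return
            _, variable = split_sites(m)
            full = variable.take_sites((variable.dosages >= 0).all(axis=0))
            biallelic = full.take_sites(
                np.asarray([s.site_class == "snp" for s in full.sites], dtype=bool)
            )
            flags = novel_alleles.classify_novel(
                biallelic, cfg.reference_groups, cfg.focal_groups
            )
            table = novel_alleles.overlap_decomposition(flags)
            with open(flags_path, "w") as fh:
                fh.write("site_id\t" + "\t".join(flags.focal_groups) + "\n")
                for j in np.flatnonzero(flags.flagged_any()):
                    fh.write(
                        flags.site_ids[j] + "\t"
                        + "\t".join(str(int(flags.flags[gi, j])) for gi in range(len(flags.focal_groups)))
                        + "\n"
                    )
            with open(counts_path, "w") as fh:
                fh.write("subset\tcount\n")
                for subset, count in sorted(table.exact_counts.items()):
                    fh.write("+".join(subset) + f"\t{count}\n")
                for g, count in table.marginals.items():
                    fh.write(f"marginal:{g}\t{count}\n")
                fh.write(f"total\t{table.total_flagged}\n")

        return [self.combined_vcf, self.groups_path], [flags_path, counts_path], fn
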