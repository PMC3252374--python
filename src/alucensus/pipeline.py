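"""Stage orchestration behind the command-line interface.

Stages (topological order): simulate -> make-probes -> call-binders ->
scan -> annotate -> summarize -> promoters. Each stage reads only files,
writes its outputs atomically (temp file + rename), and records a manifest
entry with input hashes, parameters and row counts; manifests contain no
timestamps, so re-running a completed pipeline changes no output bytes.
A missing upstream output raises an error naming the stage that produces
it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Dict, Sequence

import pandas as pd

from . import io as axio
from .census import (family_summary, kmer_frequency_table,
                     multiplicity_distribution, position_histogram)
from .pbm import aggregate_replicates, call_binders, calls_to_frame, compute_threshold
from .probes import LibraryParams, assemble_library
from .promoters import (accessibility_overlap, build_promoter_windows,
                        enrichment_cutoff, genes_with_accessible_element,
                        promoter_element_counts)
from .repeats import (annotated_hits_to_frame, assign_hits,
                      parse_repeatmasker_out)
from .scan import hits_from_bed, hits_to_bed, scan
from .simulate import SimulationConfig, write_fixture_bundle

logger = logging.getLogger("alucensus")

STAGES = ("simulate", "make-probes", "call-binders", "scan",
          "annotate", "summarize", "promoters")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Paths and parameters of one pipeline run.

    Defaults reproduce the reference analysis parameters: 13-mers, both
    strands, binder threshold at control mean + 2 SD, 5-kb promoter
    windows, enrichment cutoff at mean + 2 SD of per-gene counts.
    """

    outdir: str = "alucensus_out"
    genome: str = ""
    consensus: str = ""
    repeats: str = ""
    tss: str = ""
    accessible: str = ""
    pbm: str = ""
    k: int = 13
    strands: str = "both"
    sd_multiplier: float = 2.0
    window: int = 5000
    k_sd: float = 2.0
    seed: int = 0

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        """Flat key=value config file; '#' starts a comment."""
        values: Dict[str, str] = {}
        with open(path) as handle:
            for lineno, line in enumerate(handle, start=1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise PipelineError(f"{path}:{lineno}: expected key=value")
                key, value = (part.strip() for part in line.split("=", 1))
                values[key] = value
        cfg = cls()
        for f in fields(cls):
            if f.name in values:
                raw = values.pop(f.name)
                cast = int if f.type == "int" else float if f.type == "float" else str
                setattr(cfg, f.name, cast(raw))
        if values:
            raise PipelineError(f"unknown config keys: {sorted(values)}")
        return cfg


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _atomic_write_text(path: Path, text: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def _atomic_write_tsv(frame: pd.DataFrame, path: Path) -> None:
    _atomic_write_text(path, frame.to_csv(sep="\t", index=False))


class Pipeline:
    """Runs stages against one output directory, maintaining a manifest."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.outdir / "manifest.json"
        self.manifest: Dict[str, dict] = {}
        if self.manifest_path.exists():
            self.manifest = json.loads(self.manifest_path.read_text())

    # ---- file layout -------------------------------------------------
    def path(self, name: str) -> Path:
        return self.outdir / name

    def _input(self, configured: str, fixture_name: str, producing_stage: str,
               description: str) -> Path:
        """Resolve an input path: explicit config first, then fixture output."""
        if configured:
            p = Path(configured)
            if not p.exists():
                raise PipelineError(f"{description} input {p} does not exist")
            return p
        p = self.path("fixture") / fixture_name
        if not p.exists():
            raise PipelineError(
                f"missing {description} {p}; run the '{producing_stage}' stage first")
        return p

    def _require(self, name: str, producing_stage: str) -> Path:
        p = self.path(name)
        if not p.exists():
            raise PipelineError(
                f"missing {p.name}; run the '{producing_stage}' stage first")
        return p

    def _record(self, stage: str, inputs: Sequence[Path], params: dict,
                counts: Dict[str, int]) -> None:
        self.manifest[stage] = {
            "inputs": {str(p): _sha256(p) for p in sorted(inputs)},
            "params": params,
            "counts": counts,
        }
        _atomic_write_text(self.manifest_path,
                           json.dumps(self.manifest, indent=2, sort_keys=True) + "\n")
        logger.info("stage %s: %s", stage,
                    ", ".join(f"{k}={v}" for k, v in counts.items()))

    # ---- stages ------------------------------------------------------
    def stage_simulate(self) -> None:
        sim = SimulationConfig(seed=self.config.seed)
        paths = write_fixture_bundle(sim, self.path("fixture"))
        self._record("simulate", list(paths.values()),
                     {"seed": self.config.seed},
                     {"files": len(paths)})

    def stage_make_probes(self) -> None:
        genome_path = self._input(self.config.genome, "genome.fa", "simulate", "genome FASTA")
        consensus_path = self._input(self.config.consensus, "consensus.fa",
                                     "simulate", "consensus FASTA")
        genome = axio.read_fasta(genome_path)
        consensus = axio.read_fasta(consensus_path)
        params = LibraryParams(k=self.config.k, strands=self.config.strands)
        library = assemble_library(consensus, genome, params=params)
        _atomic_write_tsv(library.to_frame(), self.path("probes.tsv"))
        self._record("make-probes", [genome_path, consensus_path],
                     {"k": self.config.k, "strands": self.config.strands},
                     {"probes": library.raw_count,
                      "unique_sequences": library.unique_sequence_count})

    def stage_call_binders(self) -> None:
        pbm_path = self._input(self.config.pbm, "pbm_scores.tsv", "simulate", "PBM score table")
        table = axio.read_tsv(pbm_path)
        means = aggregate_replicates(table)
        control_mask = table["category"].str.startswith("random_control")
        controls = means[table.loc[control_mask, "id"]].tolist()
        threshold = compute_threshold(controls, multiplier=self.config.sd_multiplier)
        calls = call_binders(means, threshold, controls)
        sequences = dict(zip(table["id"], table["sequence"]))
        frame = calls_to_frame(calls, sequences)
        _atomic_write_tsv(frame, self.path("binding_calls.tsv"))
        binders = frame[frame["is_binder"]]
        _atomic_write_text(self.path("binder_kmers.txt"),
                           "".join(f"{s}\n" for s in sorted(set(binders["sequence"]))))
        self._record("call-binders", [pbm_path],
                     {"sd_multiplier": self.config.sd_multiplier,
                      "threshold": round(threshold.threshold, 6)},
                     {"probes": len(frame), "binders": int(frame["is_binder"].sum())})

    def stage_scan(self) -> None:
        genome_path = self._input(self.config.genome, "genome.fa", "simulate", "genome FASTA")
        binder_path = self._require("binder_kmers.txt", "call-binders")
        kmers = [line.strip() for line in binder_path.read_text().splitlines() if line.strip()]
        if not kmers:
            _atomic_write_text(self.path("hits.bed"), "")
            self._record("scan", [genome_path, binder_path],
                         {"strands": self.config.strands}, {"kmers": 0, "hits": 0})
            return
        genome = axio.read_fasta(genome_path)
        hits = scan(genome, kmers, strands=self.config.strands)
        _atomic_write_text(self.path("hits.bed"),
                           hits_to_bed(hits).to_csv(sep="\t", header=False, index=False))
        self._record("scan", [genome_path, binder_path],
                     {"strands": self.config.strands},
                     {"kmers": len(kmers), "hits": len(hits)})

    def _load_annotated(self):
        hits_path = self._require("hits.bed", "scan")
        repeats_path = self._input(self.config.repeats, "repeats.out",
                                   "simulate", "repeat annotation")
        if repeats_path.suffix == ".bed":
            from .repeats import features_from_bed
            features = features_from_bed(axio.read_bed6(repeats_path))
        else:
            features = parse_repeatmasker_out(repeats_path)
        hits = hits_from_bed(axio.read_bed6(hits_path))
        return hits, features, [hits_path, repeats_path]

    def stage_annotate(self) -> None:
        hits, features, inputs = self._load_annotated()
        annotated = assign_hits(hits, features)
        _atomic_write_tsv(annotated_hits_to_frame(annotated), self.path("annotated_hits.tsv"))
        contained = sum(1 for a in annotated if a.containment == "contained")
        self._record("annotate", inputs, {},
                     {"hits": len(annotated), "contained": contained,
                      "repeats": len(features)})

    def stage_summarize(self) -> None:
        self._require("annotated_hits.tsv", "annotate")
        hits, features, inputs = self._load_annotated()
        annotated = assign_hits(hits, features)

        freq = kmer_frequency_table(annotated)
        _atomic_write_tsv(freq, self.path("table_kmer_frequency.tsv"))

        mult, (n_elements, n_sites) = multiplicity_distribution(annotated)
        _atomic_write_tsv(mult, self.path("table_multiplicity.tsv"))

        fam = family_summary(annotated, features, level="family")
        _atomic_write_tsv(fam, self.path("table_family.tsv"))
        sub = family_summary(annotated, features, level="subfamily")
        _atomic_write_tsv(sub, self.path("table_subfamily.tsv"))
        non_alu = sub[~sub["family_or_subfamily"].isin(
            {f.subfamily for f in features if f.is_alu})]
        _atomic_write_tsv(non_alu, self.path("table_nonalu_by_count.tsv"))
        _atomic_write_tsv(
            non_alu.sort_values(["percent", "family_or_subfamily"],
                                ascending=[False, True]).reset_index(drop=True),
            self.path("table_nonalu_by_percent.tsv"))

        histogram_frames = []
        for subfamily in sorted({f.subfamily for f in features}):
            hist = position_histogram(annotated, subfamily=subfamily)
            if len(hist):
                frame = hist.reset_index()
                frame.insert(0, "subfamily", subfamily)
                histogram_frames.append(frame)
        hist_all = (pd.concat(histogram_frames, ignore_index=True) if histogram_frames
                    else pd.DataFrame(columns=["subfamily", "position", "count"]))
        _atomic_write_tsv(hist_all, self.path("position_histograms.tsv"))

        self._record("summarize", inputs, {},
                     {"kmers": len(freq), "elements_with_site": n_elements,
                      "sites": n_sites})

    def stage_promoters(self) -> None:
        self._require("annotated_hits.tsv", "annotate")
        hits, features, inputs = self._load_annotated()
        tss_path = self._input(self.config.tss, "tss.bed", "simulate", "TSS BED")
        acc_path = self._input(self.config.accessible, "dnase.bed",
                               "simulate", "accessible-region BED")
        annotated = assign_hits(hits, features)
        elements = sorted({a.repeat for a in annotated
                           if a.containment == "contained" and a.repeat.is_alu},
                          key=lambda f: f.key)
        windows = build_promoter_windows(axio.read_bed6(tss_path),
                                         window_size=self.config.window)
        stats, mean = promoter_element_counts(windows, elements)
        regions = axio.read_bed6(acc_path)
        overlap, n_accessible = accessibility_overlap(elements, regions)
        n_genes_acc = genes_with_accessible_element(windows, elements, regions)

        _atomic_write_tsv(stats, self.path("promoter_stats.tsv"))
        _atomic_write_tsv(overlap, self.path("accessibility.tsv"))
        counts = {"genes": len(stats), "elements": len(elements),
                  "accessible_elements": n_accessible,
                  "genes_with_accessible_element": n_genes_acc}
        params = {"window": self.config.window, "k_sd": self.config.k_sd,
                  "mean_elements_per_promoter": round(mean, 6) if len(stats) else None}
        if len(stats) >= 2:
            cutoff, enriched = enrichment_cutoff(stats, k_sd=self.config.k_sd)
            _atomic_write_text(self.path("enriched_genes.txt"),
                               "".join(f"{g}\n" for g in enriched))
            params["cutoff"] = cutoff
            counts["enriched_genes"] = len(enriched)
        self._record("promoters", inputs + [tss_path, acc_path], params, counts)

    # ---- dispatch ----------------------------------------------------
    def run_stage(self, stage: str) -> None:
        runners = {
            "simulate": self.stage_simulate,
            "make-probes": self.stage_make_probes,
            "call-binders": self.stage_call_binders,
            "scan": self.stage_scan,
            "annotate": self.stage_annotate,
            "summarize": self.stage_summarize,
            "promoters": self.stage_promoters,
        }
        if stage not in runners:
            raise PipelineError(f"unknown stage {stage!r}; stages are {STAGES}")
        runners[stage]()

    def run_all(self) -> None:
        for stage in STAGES:
            self.run_stage(stage)


def run_stage(stage: str, config: PipelineConfig) -> None:
    Pipeline(config).run_stage(stage)


def run_all(config: PipelineConfig) -> None:
    Pipeline(config).run_all()
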