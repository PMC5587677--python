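"""Pipeline configuration.

Plain-text key=value config with full defaulting. Every constant of the
analysis is a named key: the 200-nt lncRNA length floor, the 240-nt ORF
rule, contaminant/protein screen identity and length cut-offs (95/80 and
30), the 0.5-FPKM fallback activity threshold, DE cut-offs (alpha 0.001,
|log2FC| > 2), the GMAP-style 90% alignment identity floor, the 2-mismatch
mature-miRNA rule and the 3.0 target-expectation cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path


class PipelineConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    # run
    outdir: str = "lncwheat_out"
    seed: int = 0
    # stage-enable flags
    run_simulate: bool = True
    run_classify: bool = True
    run_express: bool = True
    run_mirnet: bool = True
    run_splice: bool = True
    # input paths (filled from outdir by the simulate stage when enabled)
    transcripts_fasta: str = ""
    contaminant_fasta: str = ""
    repeat_fasta: str = ""
    protein_fasta: str = ""
    mature_fasta: str = ""
    counts_tsv: str = ""
    alignments_gff: str = ""
    # generator parameters
    n_coding: int = 1000
    n_lncrna: int = 600
    n_contaminant: int = 100
    lncrna_gc_target: float = 0.44
    coding_orf_min: int = 300
    n_precursors: int = 20
    expr_mean_coding: float = 200.0
    expr_mean_lncrna: float = 50.0
    nb_dispersion: float = 0.1
    de_fraction: float = 0.1
    de_log2fc: float = 4.0
    n_replicates: int = 3
    n_as_loci: int = 50
    # classification constants
    min_lncrna_len: int = 200
    min_orf_nt: int = 240
    contaminant_min_identity: float = 95.0
    contaminant_min_length: int = 30
    protein_min_identity: float = 80.0
    protein_min_length: int = 30
    max_evalue: float = 1e-5
    # expression constants
    fpkm_fallback_threshold: float = 0.5
    de_alpha: float = 0.001
    de_lfc_min: float = 2.0
    de_dispersion: float = 0.1
    common_min_identity: float = 80.0
    common_min_coverage: float = 80.0
    # miRNA network constants
    mature_max_mismatch: int = 2
    precursor_flank: int = 200
    min_paired_fraction: float = 0.6
    max_mfei: float = -0.7
    expectation_cutoff: float = 3.0
    # splicing constants
    alignment_min_identity: float = 90.0

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        values = {}
        known = {f.name: f for f in fields(cls)}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise PipelineConfigError(f"{path}:{lineno}: expected KEY=VALUE")
            key, val = (x.strip() for x in line.split("=", 1))
            if key not in known:
                raise PipelineConfigError(f"{path}:{lineno}: unknown key {key!r}")
            values[key] = _coerce(val, known[key].type)
        return cls(**values)

    def apply_overrides(self, pairs: list[str]) -> "PipelineConfig":
        known = {f.name: f for f in fields(self)}
        for pair in pairs:
            if "=" not in pair:
                raise PipelineConfigError(f"override {pair!r}: expected KEY=VALUE")
            key, val = (x.strip() for x in pair.split("=", 1))
            if key not in known:
                raise PipelineConfigError(f"unknown key {key!r}")
            setattr(self, key, _coerce(val, known[key].type))
        return self

    def generator_config(self):
        from .synthetic_data import GeneratorConfig

        return GeneratorConfig(
            seed=self.seed, n_coding=self.n_coding, n_lncrna=self.n_lncrna,
            n_contaminant=self.n_contaminant, lncrna_gc_target=self.lncrna_gc_target,
            coding_orf_min=self.coding_orf_min, n_precursors=self.n_precursors,
            precursor_flank=self.precursor_flank,
            expr_mean_coding=self.expr_mean_coding, expr_mean_lncrna=self.expr_mean_lncrna,
            nb_dispersion=self.nb_dispersion, de_fraction=self.de_fraction,
            de_log2fc=self.de_log2fc, n_replicates=self.n_replicates,
            n_as_loci=self.n_as_loci,
        )

    def validate_paths(self) -> None:
        needed = []
        if not self.run_simulate:
            if self.run_classify:
                needed += [self.transcripts_fasta, self.contaminant_fasta, self.protein_fasta]
            if self.run_express:
                needed += [self.counts_tsv]
            if self.run_mirnet:
                needed += [self.mature_fasta]
            if self.run_splice:
                needed += [self.alignments_gff]
        for p in needed:
            if not p:
                raise PipelineConfigError("missing input path for an enabled stage")
            if not Path(p).exists():
                raise PipelineConfigError(f"input path does not exist: {p}")


def _coerce(val: str, ftype) -> object:
    t = str(ftype)
    if "bool" in t:
        if val.lower() in ("1", "true", "yes", "on"):
            return True
        if val.lower() in ("0", "false", "no", "off"):
            return False
        raise PipelineConfigError(f"not a boolean: {val!r}")
    if "int" in t:
        return int(val)
    if "float" in t:
        return float(val)
    return val
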