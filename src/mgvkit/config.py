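"""Pipeline configuration.

Every threshold used by a pipeline stage lives here with its published
default, grouped by stage. Configuration round-trips through a sectioned
``key = value`` file (INI syntax); command-line flags override file values.
"""

from __future__ import annotations

import configparser
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

PathLike = Union[str, Path]


@dataclass
class ClassifyConfig:
    """Viral signature classification and benchmark scoring."""
    hmm_evalue_max: float = 1e-10        # protein vs HMM hits retained below this
    fpr_weight: float = 50.0             # score = TPR - fpr_weight * FPR
    min_contig_length: int = 1000        # contigs below this are rejected
    benchmark_lengths: tuple = (1000, 2000, 5000, 10000, 20000, 50000, 100000)
    max_clauses_per_class: int = 5


@dataclass
class QualityConfig:
    """Terminal repeats, large repeats, tiering and rRNA screening."""
    min_terminal_repeat: int = 20        # bp, both DTR and ITR
    max_terminal_repeat_search: int = 5000
    large_repeat_seed: int = 100         # exact seed length for self-repeats
    large_repeat_max_span: float = 0.30  # strict > rejects the contig
    complete_min_completeness: float = 90.0   # strict >, plus closure evidence
    high_min_completeness: float = 90.0       # strict >
    medium_min_completeness: float = 50.0     # inclusive both ends: [50, 90]
    rrna_min_coverage: float = 0.70      # of the rRNA model length
    rrna_max_evalue: float = 1e-5


@dataclass
class AltCodeConfig:
    """Alternative genetic-code detection."""
    min_length: int = 10000              # strict >
    max_gc: float = 0.50                 # strict <
    margin: float = 1.10                 # alt total score >= margin * code-11 score
    min_orf_codons: int = 30             # naive ORF scorer: minimum gene length


@dataclass
class VotuConfig:
    """Species-level clustering (ANI / AF)."""
    min_ani: float = 95.0
    min_af: float = 85.0
    blast_min_identity: float = 90.0     # alignments below this are discarded
    derep_reverse_complement: bool = True
    aligner_kmer: int = 15
    aligner_min_score: int = 25          # Kadane segment score (match +1 / mismatch -1)
    aligner_max_length: int = 100000     # built-in path only guaranteed below this


@dataclass
class AAIConfig:
    """Genus/family clustering from AAI + gene sharing via Markov clustering."""
    hit_evalue_max: float = 1e-5
    family_min_aai: float = 20.0
    family_min_shared: float = 10.0
    family_inflation: float = 1.2
    genus_min_aai: float = 50.0
    genus_min_shared: float = 20.0
    genus_inflation: float = 2.0
    mcl_prune: float = 1e-5
    mcl_max_iterations: int = 100
    mcl_convergence: float = 1e-6


@dataclass
class TaxonomyConfig:
    """Consensus taxonomy from reference protein hits."""
    min_query_cover: float = 50.0
    min_subject_cover: float = 50.0
    max_evalue: float = 1e-5
    fallback_bits_fraction: float = 0.75  # "within 25% of the top hit"
    min_agreement: float = 0.70           # strict >
    family_min_proteins: int = 2
    family_min_identity: float = 30.0     # strict >
    genus_min_proteins: int = 3
    genus_min_mean_identity: float = 40.0 # strict >


@dataclass
class HostLinkConfig:
    """CRISPR spacer and genome-match host prediction."""
    spacer_max_edits: int = 1             # combined mismatches + gaps
    spacer_min_coverage: float = 0.95     # of the spacer length
    genome_match_min_length: int = 1000
    genome_match_min_identity: float = 96.0
    host_fraction_min: float = 0.50       # contigs below this are decontaminated away
    min_agreement: float = 0.70           # strict >


@dataclass
class PhyloConfig:
    """Marker concatenation, diversity and core-SNP matrices."""
    max_gap_fraction: float = 0.50        # columns with >= this gap fraction removed
    min_markers: int = 3
    min_column_fraction: float = 0.05     # strict >
    snp_min_position_coverage: float = 0.50  # inclusive
    snp_min_genome_coverage: float = 0.50    # inclusive


@dataclass
class PipelineConfig:
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    quality: QualityConfig = field(default_factory=QualityConfig)
    altcode: AltCodeConfig = field(default_factory=AltCodeConfig)
    votu: VotuConfig = field(default_factory=VotuConfig)
    aai: AAIConfig = field(default_factory=AAIConfig)
    taxonomy: TaxonomyConfig = field(default_factory=TaxonomyConfig)
    hostlink: HostLinkConfig = field(default_factory=HostLinkConfig)
    phylo: PhyloConfig = field(default_factory=PhyloConfig)

    def save(self, path: PathLike) -> None:
        parser = configparser.ConfigParser()
        for section_field in dataclasses.fields(self):
            section = getattr(self, section_field.name)
            parser[section_field.name] = {
                f.name: _fmt(getattr(section, f.name))
                for f in dataclasses.fields(section)
            }
        with open(path, "w") as handle:
            parser.write(handle)

    @classmethod
    def load(cls, path: PathLike) -> "PipelineConfig":
        parser = configparser.ConfigParser()
        with open(path) as handle:
            parser.read_file(handle)
        config = cls()
        for section_field in dataclasses.fields(config):
            if section_field.name not in parser:
                continue
            section = getattr(config, section_field.name)
            for f in dataclasses.fields(section):
                if f.name in parser[section_field.name]:
                    raw = parser[section_field.name][f.name]
                    setattr(section, f.name, _parse(raw, getattr(section, f.name)))
        return config


def _fmt(value) -> str:
    if isinstance(value, tuple):
        return ",".join(str(v) for v in value)
    return str(value)


def _parse(raw: str, default):
    if isinstance(default, bool):
        return raw.strip().lower() in ("1", "true", "yes", "on")
    if isinstance(default, int):
        return int(raw)
    if isinstance(default, float):
        return float(raw)
    if isinstance(default, tuple):
        return tuple(int(v) for v in raw.split(","))
    return raw
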