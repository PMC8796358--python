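"""Pipeline orchestration: two-stage alignment runs and replicated experiments.

A single global seed deterministically derives per-stage seeds (stable
hash offsets), so a whole run — simulation, fragmentation, backbone
sampling, support alignments — reproduces byte-identically from one
integer.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence as TypingSequence

import pandas as pd
from skbio import TreeNode

from . import __version__
from .backbone import BackboneConfig, split_dataset
from .dc_aligner import MergeConfig, Scoring, align_backbone, align_unaligned
from .ehmm import EnsembleConfig, add_queries
from .evaluate import error_report, pearson_r
from .fragmenter import FragmentationProfile
from .msa_core import Alignment, Sequence, restrict_alignment
from .simdata import SimulationConfig, make_benchmark


def derive_seed(master: int, stage: str) -> int:
    """Stage seed from the global seed: stable, independent, < 2**31."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    seed: int = 0
    backbone: BackboneConfig | None = None
    merge: MergeConfig | None = None
    ensemble: EnsembleConfig | None = None
    scoring: Scoring = Scoring()
    max_subset_size: int = 50

    def __post_init__(self) -> None:
        if self.backbone is None:
            self.backbone = BackboneConfig(seed=derive_seed(self.seed, "backbone"))
        if self.merge is None:
            self.merge = MergeConfig(seed=derive_seed(self.seed, "merge"))
        if self.ensemble is None:
            self.ensemble = EnsembleConfig(seed=derive_seed(self.seed, "ensemble"))


@dataclass
class PipelineResult:
    final: Alignment
    backbone_alignment: Alignment
    backbone_ids: set[str]
    query_ids: set[str]
    manifest: dict = field(default_factory=dict)


def run_pipeline(
    seqs: TypingSequence[Sequence],
    config: PipelineConfig | None = None,
    known_fragment_ids: set[str] | None = None,
    backbone_alignment: Alignment | None = None,
    backbone_tree: TreeNode | None = None,
) -> PipelineResult:
    """Split -> align backbone -> add queries.

    A precomputed ``backbone_alignment`` (and optionally its tree) skips
    stage 1, mirroring the use of an external backbone aligner whose
    output is handed to the query-placement stage.
    """
    config = config or PipelineConfig()
    by_id = {s.id: s for s in seqs}
    if backbone_alignment is not None:
        bb_ids = set(backbone_alignment.rows)
        missing = bb_ids - set(by_id)
        if missing:
            raise ValueError(
                f"backbone alignment rows not in input: {sorted(missing)[:5]}"
            )
        query_ids = set(by_id) - bb_ids
        bb_aln = backbone_alignment
    else:
        bb_ids, query_ids = split_dataset(
            seqs, known_fragment_ids=known_fragment_ids, config=config.backbone
        )
        bb_seqs = [s for s in seqs if s.id in bb_ids]
        bb_aln = align_backbone(
            bb_seqs,
            max_subset_size=config.max_subset_size,
            merge_config=config.merge,
            scoring=config.scoring,
        )
    queries = [s for s in seqs if s.id in query_ids]
    final = add_queries(bb_aln, queries, config.ensemble, tree=backbone_tree)
    # restore input row order
    final = Alignment(
        {s.id: final.rows[s.id] for s in seqs}, final.insertion_columns
    )
    manifest = {
        "tool": "fragalign",
        "version": __version__,
        "seed": config.seed,
        "n_sequences": len(seqs),
        "n_backbone": len(bb_ids),
        "n_queries": len(query_ids),
        "backbone_provided": backbone_alignment is not None,
        "backbone_size": config.backbone.backbone_size,
        "max_subset_size": config.max_subset_size,
        "inflation": config.merge.inflation,
        "min_subset_size": config.ensemble.min_subset_size,
        "input_digest": _digest(seqs),
    }
    return PipelineResult(final, bb_aln, set(bb_ids), set(query_ids), manifest)


def _digest(seqs: TypingSequence[Sequence]) -> str:
    h = hashlib.sha256()
    for s in seqs:
        h.update(s.id.encode())
        h.update(b"\0")
        h.update(s.residues.encode())
        h.update(b"\n")
    return h.hexdigest()[:16]


@dataclass
class ExperimentConfig:
    n_replicates: int = 10
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    profiles: tuple[str, ...] = ("HF", "LF")
    variants: tuple[str, ...] = ("two_stage", "one_stage")
    seed: int = 0
    max_subset_size: int = 50
    min_subset_size: int = 10


def run_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Replicated simulation study: per-replicate SPFN/SPFP for each variant.

    Each replicate simulates a dataset, fragments it under each profile,
    aligns it with each variant, and scores against the fragmented truth.
    For the two-stage variant the backbone alignment's own error is also
    recorded, enabling the backbone-vs-final error correlation.
    """
    records = []
    for rep in range(config.n_replicates):
        rep_seed = derive_seed(config.seed, f"rep{rep}")
        sim = SimulationConfig(
            n_taxa=config.sim.n_taxa,
            root_length=config.sim.root_length,
            substitution_rate=config.sim.substitution_rate,
            indel_rate=config.sim.indel_rate,
            indel_length_mean=config.sim.indel_length_mean,
            seed=rep_seed,
        )
        for profile_name in config.profiles:
            profile = FragmentationProfile.named(
                profile_name, seed=derive_seed(rep_seed, f"frag-{profile_name}")
            )
            bundle = make_benchmark(sim, profile)
            truth = bundle.fragmented_truth
            for variant in config.variants:
                row = {
                    "replicate": rep,
                    "profile": profile_name,
                    "variant": variant,
                    "n_taxa": sim.n_taxa,
                }
                if variant == "two_stage":
                    pcfg = PipelineConfig(
                        seed=derive_seed(rep_seed, f"pipe-{profile_name}"),
                        max_subset_size=config.max_subset_size,
                        ensemble=EnsembleConfig(
                            min_subset_size=config.min_subset_size,
                            seed=derive_seed(rep_seed, "ens"),
                        ),
                    )
                    result = run_pipeline(
                        bundle.sequences,
                        pcfg,
                        known_fragment_ids=bundle.fragment_ids,
                    )
                    est = result.final
                    bb_truth = restrict_alignment(truth, result.backbone_ids)
                    bb_rep = error_report(bb_truth, result.backbone_alignment)
                    row["backbone_spfn"] = bb_rep.spfn
                    row["backbone_spfp"] = bb_rep.spfp
                    row["backbone_avg_error"] = bb_rep.avg_error
                elif variant == "one_stage":
                    est = align_unaligned(bundle.sequences)
                else:
                    raise ValueError(f"unknown variant {variant!r}")
                rep_err = error_report(truth, est)
                row["spfn"] = rep_err.spfn
                row["spfp"] = rep_err.spfp
                row["avg_error"] = rep_err.avg_error
                records.append(row)
    return pd.DataFrame.from_records(records)


def backbone_final_correlation(table: pd.DataFrame) -> dict[str, float]:
    """Pearson r between backbone and final average error, per profile."""
    out = {}
    two = table[table["variant"] == "two_stage"]
    for profile_name, grp in two.groupby("profile"):
        if len(grp) >= 2:
            try:
                out[str(profile_name)] = pearson_r(
                    grp["backbone_avg_error"], grp["avg_error"]
                )
            except ValueError:
                pass
    return out


def manifest_to_json(manifest: dict) -> str:
    return json.dumps(manifest, indent=2, sort_keys=True)
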