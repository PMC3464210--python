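"""End-to-end orchestration: simulate -> detect -> encode -> phylo -> annotate.

One seeded configuration drives every stage; a run manifest records the
configuration hash, seeds and output digests so identical manifests
imply byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np

from . import io as ikio
from .annotate import (
    define_element_boundaries,
    discover_repeat_candidate,
    find_repeat_copies,
)
from .catalog import build_segment_map, encode_karyotype, gambiae_complex_catalog
from .matepair import (
    LibrarySpec,
    ReferenceIndex,
    classify_pairs,
    cluster_and_call,
    map_pairs,
)
from .phylo import X_STATE_OPTIONS, best_scenario, complex_matrix
from .rearrange import pairwise_distance_matrix
from .simulate import (
    build_reference_arms,
    complex_event_tree,
    evolve_karyotypes,
    plant_mite,
    simulate_matepair_pairs,
    simulate_toy_inversion,
)
from ._seq import random_dna

log = logging.getLogger("inversionkit")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "simulate": {"segment_length": 20_000, "junction_gap": 0},
    "matepair": {
        "reference_length": 400_000,
        "breakpoints": [94_800, 298_400],
        "coverage": 20.0,
        "libraries": [
            {"name": "mp2k", "insert_size": 2000, "insert_sd": 0.0},
            {"name": "mp3k", "insert_size": 3000, "insert_sd": 0.0},
            {"name": "mp5k", "insert_size": 5000, "insert_sd": 0.0},
        ],
        "min_support": 2,
    },
    "mite": {
        "genome_length": 120_000,
        "element_length": 350,
        "tsd_length": 3,
        "copies": 12,
    },
    "phylo": {"outgroup_x": list(X_STATE_OPTIONS)},
}


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    outputs: dict[str, str]

    def to_json(self) -> str:
        return json.dumps(
            {"config_hash": self.config_hash, "seed": self.seed,
             "outputs": self.outputs},
            indent=2, sort_keys=True,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _merged(config: dict | None) -> dict:
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (config or {}).items():
        if isinstance(val, dict) and isinstance(merged.get(key), dict):
            merged[key].update(val)
        else:
            merged[key] = val
    return merged


def run_pipeline(config: dict | None, out_dir: str | Path) -> RunManifest:
    """Run every stage on one seeded configuration; returns the manifest."""
    cfg = _merged(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    catalog = gambiae_complex_catalog()
    outputs: dict[str, Path] = {}

    # ---- simulate: complex karyotype history ------------------------------
    stage = "simulate"
    try:
        rng = np.random.default_rng(seed)
        arms = build_reference_arms(
            catalog, segment_length=int(cfg["simulate"]["segment_length"]), rng=rng
        )
        tree, root = complex_event_tree()
        genomes, truth = evolve_karyotypes(
            arms, tree, catalog, root_states=root,
            junction_gap=int(cfg["simulate"]["junction_gap"]), rng=rng,
        )
        ikio.write_karyotypes_tsv(out / "karyotypes.tsv", truth.states)
        outputs["karyotypes.tsv"] = out / "karyotypes.tsv"
        log.info("simulate: %d species genomes", len(genomes))
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # ---- encode + distances ----------------------------------------------
    stage = "encode"
    try:
        maps = {arm: build_segment_map(catalog, arm) for arm in catalog.arms}
        perms = {
            sp: encode_karyotype(st, maps, catalog)
            for sp, st in truth.states.items()
        }
        ikio.write_permutations_json(out / "perms.json", perms)
        outputs["perms.json"] = out / "perms.json"
        dm = pairwise_distance_matrix(perms)
        dm.to_frame().to_csv(out / "distances.tsv", sep="\t")
        outputs["distances.tsv"] = out / "distances.tsv"
        log.info("encode: %d karyotypes, distance matrix written", len(perms))
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # ---- phylo: scenario analysis ----------------------------------------
    stage = "phylo"
    try:
        options = cfg["phylo"].get("outgroup_x")
        if not options:
            raise ValueError("no outgroup X arrangements configured")
        comparison = best_scenario(complex_matrix(), options)
        report = {
            "winner": comparison.winners[0] if comparison.winners else None,
            "winners": comparison.winners,
            "scenarios": [
                {
                    "scenario": r.scenario,
                    "total_events": r.total_events,
                    "all_single_origin": r.all_single_origin,
                    "origins": r.origins,
                    "n_best_topologies": len(r.best_topologies),
                    "best_topologies": r.newicks(),
                }
                for r in comparison.results
            ],
        }
        (out / "scenarios.json").write_text(json.dumps(report, indent=2))
        outputs["scenarios.json"] = out / "scenarios.json"
        log.info("phylo: winner %s", report["winner"])
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # ---- matepair: toy inversion detection -------------------------------
    stage = "matepair"
    try:
        mp = cfg["matepair"]
        rng = np.random.default_rng(seed + 1)
        toy = simulate_toy_inversion(
            rng,
            reference_length=int(mp["reference_length"]),
            breakpoints=tuple(mp["breakpoints"]),
        )
        libs = {
            d["name"]: LibrarySpec(d["name"], int(d["insert_size"]),
                                   float(d.get("insert_sd", 0.0)))
            for d in mp["libraries"]
        }
        index = ReferenceIndex(toy.reference)
        alignments = []
        for lib in libs.values():
            pairs = simulate_matepair_pairs(
                toy.derived, lib, float(mp["coverage"]) / len(libs), rng
            )
            al = map_pairs(pairs, index, lib)
            alignments.extend(al)
        classify_pairs(alignments, libs)
        calls = cluster_and_call(alignments, libs,
                                 min_support=int(mp["min_support"]))
        ikio.write_calls_bed(out / "calls.bed", calls)
        ikio.write_calls_tsv(out / "calls.tsv", calls)
        outputs["calls.bed"] = out / "calls.bed"
        outputs["calls.tsv"] = out / "calls.tsv"
        log.info("matepair: %d pairs -> %d calls (true breakpoints %s)",
                 len(alignments), len(calls), toy.breakpoints)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # ---- mite: boundary/TSD recovery -------------------------------------
    stage = "mite"
    try:
        mc = cfg["mite"]
        rng = np.random.default_rng(seed + 2)
        genome = random_dna(int(mc["genome_length"]), rng)
        genome, element, planted = plant_mite(
            genome, int(mc["element_length"]), int(mc["tsd_length"]),
            int(mc["copies"]), rng,
        )
        candidate = discover_repeat_candidate(genome)
        copies = find_repeat_copies(candidate, genome, min_length=100)
        model = define_element_boundaries(genome, copies, name="sim_mite")
        payload = {
            "name": model.name,
            "tsd_length": model.tsd_length,
            "tsd_votes": {str(k): v for k, v in model.tsd_votes.items()},
            "consensus_length": len(model.consensus),
            "n_copies": len(model.copies),
            "true_tsd_length": int(mc["tsd_length"]),
            "true_element_length": int(mc["element_length"]),
        }
        (out / "mite.json").write_text(json.dumps(payload, indent=2))
        outputs["mite.json"] = out / "mite.json"
        log.info("mite: tsd_length=%d from %d copies",
                 model.tsd_length, len(model.copies))
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # ---- manifest ---------------------------------------------------------
    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()
    ).hexdigest()
    manifest = RunManifest(
        config_hash=cfg_hash,
        seed=seed,
        outputs={name: _sha256(path) for name, path in sorted(outputs.items())},
    )
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
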