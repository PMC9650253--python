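"""End-to-end pipeline: data -> compositions -> i-means -> transactions
-> rules -> network, driven by one validated YAML/dict config.

Every stage writes its artifacts under the configured output
directory, and a run manifest (parameters, derived per-stage seeds,
SHA-256 digests of every output) makes reruns auditably bit-exact:
the same config always produces the same manifest.  The single global
seed is expanded into independent per-stage seeds through
``numpy.random.SeedSequence([seed, stage_index])``.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import apriori, discretize, imeans, network, preprocess, synth

__all__ = ["PipelineError", "DEFAULT_CONFIG", "load_config", "run_pipeline"]

log = logging.getLogger("omnirule")

_STAGES = ("synth", "preprocess", "imeans_nmr", "imeans_taxa", "encode", "mine", "graph")

DEFAULT_CONFIG: dict[str, Any] = {
    "version": 1,
    "seed": 0,
    "out_dir": "omnirule_out",
    "synth": None,  # SynthConfig fields; mutually exclusive with `inputs`
    "inputs": None,  # {nmr, taxa, phenotypes, metadata} CSV paths
    "preprocess": {
        "standard_feature": None,  # e.g. "DSS": divide by internal standard first
        "drop_extreme": {
            "enabled": True,
            "max_mass_features": 2,
            "mass_threshold": 0.99,
        },
    },
    "imeans": {
        "k_min": 2,
        "k_max": 6,
        "repeats": 5,
        "threshold": 0.9,
        "test_size": 0.3,
        "n_estimators": 100,
        "scale_for_kmeans": True,
        "importance": "impurity",
    },
    "encode": {"mode": "within_sample", "quarter": "floor", "strata_column": "strain"},
    "mine": {
        "min_support": 0.1,
        "min_confidence": 0.5,
        "min_lift": 1.0,
        "max_len": 4,
    },
    "graph": {"focus": [], "radius": 1, "format": "gexf"},
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


def _merge_validate(defaults: Any, given: Any, path: str) -> Any:
    """Recursively overlay ``given`` on ``defaults``, rejecting unknown keys."""
    if given is None:
        return copy.deepcopy(defaults)
    if isinstance(defaults, Mapping):
        if not isinstance(given, Mapping):
            raise ValueError(f"config key {path or '<root>'} must be a mapping")
        out = {}
        unknown = set(given) - set(defaults)
        if unknown and path not in ("synth", "inputs"):
            raise ValueError(
                f"unknown config key(s) under {path or '<root>'}: {sorted(unknown)}"
            )
        source = given if path in ("synth", "inputs") else defaults
        for key in source:
            sub_default = defaults.get(key) if key in defaults else None
            out[key] = _merge_validate(
                sub_default, given.get(key), f"{path}.{key}" if path else key
            )
        return out
    return copy.deepcopy(given)


def load_config(config: str | Path | Mapping[str, Any]) -> dict[str, Any]:
    """Load and validate a pipeline config from a YAML path or a mapping.

    Unknown keys are rejected; omitted keys take documented defaults.
    Exactly one of ``synth`` (generate inputs) and ``inputs`` (CSV
    paths) must be set.
    """
    if isinstance(config, (str, Path)):
        raw = yaml.safe_load(Path(config).read_text())
    else:
        raw = dict(config)
    cfg = _merge_validate(DEFAULT_CONFIG, raw, "")
    if cfg["version"] != 1:
        raise ValueError(f"unsupported config version {cfg['version']!r}")
    if (cfg["synth"] is None) == (cfg["inputs"] is None):
        raise ValueError("exactly one of 'synth' and 'inputs' must be given")
    if cfg["inputs"] is not None:
        required = {"nmr", "taxa", "phenotypes", "metadata"}
        missing = required - set(cfg["inputs"])
        if missing:
            raise ValueError(f"inputs missing table path(s): {sorted(missing)}")
        for name in required:
            p = Path(cfg["inputs"][name])
            if not p.exists():
                raise FileNotFoundError(f"input {name!r} not found: {p}")
    return cfg


def _stage_seed(base_seed: int, stage: str) -> int:
    idx = _STAGES.index(stage)
    ss = np.random.SeedSequence([int(base_seed), idx])
    return int(ss.generate_state(1)[0] % 2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _imeans_stage(table: pd.DataFrame, params: Mapping[str, Any], seed: int):
    p = dict(params)
    k_range = (p.pop("k_min"), p.pop("k_max"))
    return imeans.run_imeans(table.T, k_range=k_range, seed=seed, **p)


def _imeans_json(res: imeans.IMeansResult) -> dict[str, Any]:
    return {
        "chosen_k": res.chosen_k,
        "fallback": res.fallback,
        "labels": {str(k): int(v) for k, v in res.labels.items()},
        "curve": {
            str(k): {"mean": m, "sd": s}
            for k, m, s in zip(res.curve.ks, res.curve.mean, res.curve.sd)
        },
        "importances": [[f, v] for f, v in res.importances],
    }


def run_pipeline(config: str | Path | Mapping[str, Any]) -> dict[str, Any]:
    """Run every stage in order and return the manifest.

    Inputs are never mutated; each stage writes fresh files under
    ``out_dir``.  Defaults the user did not set are logged so every
    assumption of a run is on record.  Any stage error aborts with the
    stage name in the message.
    """
    cfg = load_config(config)
    given = (
        yaml.safe_load(Path(config).read_text())
        if isinstance(config, (str, Path))
        else dict(config)
    )
    for key, value in cfg.items():
        if key not in given:
            log.info("config default used: %s = %r", key, value)

    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    base_seed = int(cfg["seed"])
    outputs: dict[str, Path] = {}
    stage_seeds = {s: _stage_seed(base_seed, s) for s in _STAGES}

    def run_stage(name, fn):
        try:
            return fn()
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    # --- inputs -----------------------------------------------------
    def stage_inputs():
        if cfg["synth"] is not None:
            params = dict(cfg["synth"])
            params.setdefault("seed", stage_seeds["synth"])
            params["planted_rules"] = tuple(
                synth.PlantedRule(**r) if isinstance(r, Mapping) else r
                for r in params.get("planted_rules", ())
            )
            ds = synth.generate_dataset(synth.SynthConfig(**params))
            for p in synth.write_dataset(ds, out_dir / "synth"):
                outputs[f"synth/{p.name}"] = p
            return ds.nmr, ds.taxa, ds.phenotypes, ds.metadata
        paths = cfg["inputs"]
        rt = dict(index_col=0, float_precision="round_trip")
        return (
            pd.read_csv(paths["nmr"], **rt),
            pd.read_csv(paths["taxa"], **rt),
            pd.read_csv(paths["phenotypes"], **rt),
            pd.read_csv(paths["metadata"], index_col=0),
        )

    nmr_raw, taxa_raw, pheno, meta = run_stage("synth", stage_inputs)

    # --- preprocess -------------------------------------------------
    def stage_preprocess():
        nmr = nmr_raw
        std = cfg["preprocess"]["standard_feature"]
        if std is not None:
            nmr = preprocess.normalize_to_standard(nmr, std)
        nmr_comp = preprocess.composition_normalize(nmr)
        taxa_comp = preprocess.composition_normalize(taxa_raw)
        dropped: list[str] = []
        de = cfg["preprocess"]["drop_extreme"]
        if de["enabled"]:
            taxa_comp, dropped = preprocess.drop_extreme_samples(
                taxa_comp, de["max_mass_features"], de["mass_threshold"]
            )
            if dropped:
                log.info("dropped extreme sample(s): %s", dropped)
        nmr_comp.to_csv(out_dir / "nmr_composition.csv")
        taxa_comp.to_csv(out_dir / "taxa_composition.csv")
        outputs["nmr_composition.csv"] = out_dir / "nmr_composition.csv"
        outputs["taxa_composition.csv"] = out_dir / "taxa_composition.csv"
        return nmr_comp, taxa_comp, dropped

    nmr_comp, taxa_comp, dropped = run_stage("preprocess", stage_preprocess)

    # --- i-means per omic -------------------------------------------
    results = {}
    for omic, table in (("nmr", nmr_comp), ("taxa", taxa_comp)):
        def stage_im(omic=omic, table=table):
            res = _imeans_stage(table, cfg["imeans"], stage_seeds[f"imeans_{omic}"])
            p = out_dir / f"imeans_{omic}.json"
            p.write_text(json.dumps(_imeans_json(res), indent=2))
            outputs[p.name] = p
            return res
        results[omic] = run_stage(f"imeans_{omic}", stage_im)

    # --- encode -----------------------------------------------------
    def stage_encode():
        enc_cfg = cfg["encode"]
        index = nmr_comp.columns
        enc_nmr = discretize.encode_within_sample(
            nmr_comp, namespace="nmr", quarter=enc_cfg["quarter"],
            mode=enc_cfg["mode"],
        )
        enc_taxa = discretize.encode_within_sample(
            taxa_comp, namespace="taxa", quarter=enc_cfg["quarter"],
            mode=enc_cfg["mode"],
        )
        enc_pheno = discretize.encode_within_strata(
            pheno.loc[index], meta.loc[index, enc_cfg["strata_column"]],
            namespace="pheno", quarter=enc_cfg["quarter"],
        )
        # dropped extreme samples carry no taxa items but stay in the set
        enc_taxa = discretize.QuartileEncoding(
            labels=enc_taxa.labels.reindex(index), namespace=enc_taxa.namespace
        )
        classes = {
            "NMR_class": results["nmr"].labels.reindex(index),
            "NGS_class": results["taxa"].labels.reindex(index),
        }
        meta_items = meta.loc[index].drop(columns=["strain"], errors="ignore")
        tx = discretize.build_transactions(
            [enc_nmr, enc_taxa, enc_pheno], metadata=meta_items, classes=classes
        )
        p = out_dir / "transactions.basket"
        tx.write_basket(p)
        outputs[p.name] = p
        return tx

    transactions = run_stage("encode", stage_encode)

    # --- mine -------------------------------------------------------
    def stage_mine():
        rules = apriori.mine_rules(transactions, **cfg["mine"])
        p = out_dir / "rules.csv"
        apriori.write_rules_csv(rules, p)
        outputs[p.name] = p
        return rules

    rules = run_stage("mine", stage_mine)

    # --- graph ------------------------------------------------------
    def stage_graph():
        gcfg = cfg["graph"]
        g = network.rules_to_graph(rules) if rules else network.rules_to_graph([])
        suffix = gcfg["format"]
        p = network.export_graph(g, out_dir / f"rule_network.{suffix}", suffix)
        outputs[p.name] = p
        if gcfg["focus"]:
            ego = network.ego_subgraph(g, gcfg["focus"], radius=gcfg["radius"])
            p2 = network.export_graph(ego, out_dir / f"rule_network_ego.{suffix}", suffix)
            outputs[p2.name] = p2
        return g

    graph = run_stage("graph", stage_graph)

    manifest = {
        "config": cfg,
        "stage_seeds": stage_seeds,
        "dropped_samples": dropped,
        "chosen_k": {omic: results[omic].chosen_k for omic in results},
        "n_transactions": len(transactions),
        "n_rules": len(rules),
        "n_graph_nodes": graph.number_of_nodes(),
        "n_graph_edges": graph.number_of_edges(),
        "outputs": {name: _sha256(p) for name, p in sorted(outputs.items())},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
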