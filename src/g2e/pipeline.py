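"""End-to-end pipeline: simulate or load inputs, build the network,
cluster, compute indices and ecological matrices, run the permutation
statistics, and write all artifacts plus a run manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np

from . import __version__, ecology, io
from .indices import pairwise_index_matrix
from .mantel import matrix_regression, partial_mantel, variance_partition
from .mcl import filter_catalog, mcl_cluster
from .network import build_reference_network, normalize_weights
from .synthetic import SimulationConfig, simulate_dataset

logger = logging.getLogger("g2e")

__all__ = ["run_pipeline", "parse_config"]


def parse_config(path: str | Path) -> dict:
    """Flat key=value config file; '#' starts a comment."""
    cfg: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"bad config line: {line!r}")
        key, val = line.split("=", 1)
        cfg[key.strip()] = val.strip()
    return cfg


def _coerce_sim_config(cfg: dict, seed: int | None) -> SimulationConfig:
    fields = {f.name: f.type for f in dataclasses.fields(SimulationConfig)}
    kwargs = {}
    for key, val in cfg.items():
        if key not in fields:
            continue
        default = SimulationConfig.__dataclass_fields__[key].default
        if isinstance(default, bool):
            kwargs[key] = val.lower() in ("1", "true", "yes")
        elif isinstance(default, int):
            kwargs[key] = int(val)
        elif isinstance(default, float):
            kwargs[key] = float(val)
        elif isinstance(default, tuple):
            kwargs[key] = tuple(int(x) for x in val.split(","))
        else:
            kwargs[key] = val
    if seed is not None:
        kwargs["seed"] = seed
    return SimulationConfig(**kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: dict,
    out_dir: str | Path,
    seed: int | None = None,
) -> Path:
    """Run every stage and write artifacts under ``out_dir``.

    ``config`` either sets ``simulate=true`` (with SimulationConfig
    keys) or provides paths ``links``, ``content``, ``otu``, ``tree``.
    Statistical settings: ``threshold`` (275), ``inflation`` (4),
    ``min_set_size`` (4), ``n_perm`` (9999).

    Returns the output directory; a ``manifest.json`` records
    parameters, input hashes, seed and stage timings. No stage
    mutates its inputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest: dict = {
        "command": "run_pipeline",
        "parameters": dict(config),
        "seed": seed,
        "version": __version__,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "inputs": {},
        "stages": {},
        "status": "running",
    }

    def stage(name: str):
        manifest["stages"][name] = {"t": round(time.time() - t0, 3)}
        logger.info("stage %s at %.2fs", name, time.time() - t0)

    try:
        if str(config.get("simulate", "")).lower() in ("1", "true", "yes"):
            stage("simulate")
            sim_cfg = _coerce_sim_config(config, seed)
            ds = simulate_dataset(sim_cfg)
            links, content, otu = ds.links, ds.content, ds.otu_table
            tree = ds.tree
            io.write_link_table(links, out / "links.tsv")
            io.write_genome_content(content, out / "content.tsv")
            io.write_otu_table(otu, out / "otu.tsv")
            tree.write(path=str(out / "tree.nwk"), schema="newick")
        else:
            stage("load")
            for key in ("links", "content", "otu", "tree"):
                if key not in config:
                    raise FileNotFoundError(
                        f"config missing input path {key!r}"
                    )
                p = Path(config[key])
                if not p.exists():
                    raise FileNotFoundError(f"{key} file not found: {p}")
                manifest["inputs"][key] = _sha256(p)
            links = io.read_link_table(config["links"])
            content = io.read_genome_content(config["content"])
            otu = io.read_otu_table(config["otu"])
            tree = ecology.read_tree(config["tree"])

        threshold = int(config.get("threshold", 275))
        inflation = float(config.get("inflation", 4.0))
        min_size = int(config.get("min_set_size", 4))
        n_perm = int(config.get("n_perm", 9999))

        stage("network")
        net = normalize_weights(
            build_reference_network(links, threshold), threshold
        )
        edges = sorted(
            (a, b, net.graph.edges[a, b]["score"],
             net.graph.edges[a, b]["weight"])
            for a, b in net.edges
        )
        with open(out / "network.tsv", "w") as fh:
            fh.write("family_a\tfamily_b\tscore\tweight\n")
            for a, b, s, w in edges:
                fh.write(f"{a}\t{b}\t{s}\t{w:.10g}\n")

        stage("cluster")
        catalog = filter_catalog(mcl_cluster(net, inflation), min_size)
        io.write_catalog(catalog, out / "catalog.tsv")

        stage("indices")
        sim_m, assoc_m = pairwise_index_matrix(
            content, catalog, net, min_size=min_size
        )
        io.write_square_matrix(sim_m, out / "similarity.tsv")
        io.write_square_matrix(assoc_m, out / "association.tsv")

        stage("ecology")
        filtered = ecology.filter_otu_table(otu)
        cooc = ecology.jaccard_cooccurrence(filtered)
        io.write_square_matrix(cooc, out / "cooccurrence.tsv")
        phylo = ecology.cophenetic_distances(tree)
        io.write_square_matrix(phylo, out / "phylodist.tsv")

        stage("stats")
        cooc_a, sim_a, assoc_a, phylo_a = ecology.align_matrices(
            [cooc, sim_m, assoc_m, phylo]
        )
        rng = np.random.default_rng(seed)
        results: dict = {"n_genomes": cooc_a.n, "n_perm": n_perm}
        for name, mat in (
            ("genome_content_similarity", sim_a),
            ("functional_association", assoc_a),
        ):
            pm = partial_mantel(
                mat, cooc_a, phylo_a, n_perm=n_perm, seed=rng
            )
            results[f"partial_mantel_{name}"] = {
                "r": pm.r, "p": pm.p, "n_perm": pm.n_perm,
            }
        reduced = matrix_regression(
            cooc_a, [phylo_a], n_perm=n_perm, seed=rng,
            predictor_names=["phylogeny"],
        )
        full = matrix_regression(
            cooc_a, [phylo_a, sim_a, assoc_a], n_perm=n_perm, seed=rng,
            predictor_names=[
                "phylogeny", "genome_content_similarity",
                "functional_association",
            ],
        )
        results["regression_phylogeny_only"] = _regression_dict(reduced)
        results["regression_full"] = _regression_dict(full)
        results["variance_explained_by_indices"] = (
            variance_partition(full, reduced)
        )
        with open(out / "results.json", "w") as fh:
            json.dump(results, fh, indent=2)

        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        raise
    finally:
        manifest["elapsed_s"] = round(time.time() - t0, 3)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return out


def _regression_dict(res) -> dict:
    return {
        "predictors": list(res.predictor_names),
        "coefficients": [float(c) for c in res.coefficients],
        "t_statistics": [float(t) for t in res.t_statistics],
        "p_values": [None if np.isnan(p) else float(p)
                     for p in res.p_values],
        "f_statistic": res.f_statistic,
        "f_p_value": res.f_p_value,
        "r_squared": res.r_squared,
    }
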