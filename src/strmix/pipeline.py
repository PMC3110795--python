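"""Config-driven orchestration of the full analysis.

A run executes: generate (or load) genotypes -> locus QC -> admixture
clustering replicated over a K range -> delta-K model choice -> per-locale
cluster means -> correspondence analysis -> chord-distance / NJ locale
tree -> information-content locus ranking -> mito-nuclear report.  Every
artifact is written as plain text and listed in a JSON manifest carrying
the config hash and seed; identical configs produce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import admixture, informativeness, io, mitonuclear, ordination, qc
from .simulate import SimConfig, simulate_dataset

log = logging.getLogger("strmix")

DEFAULT_STAGES = ("qc", "admixture", "deltak", "fca", "tree", "sic", "mito")

_CONFIG_KEYS = {
    "seed", "out_dir", "simulate", "genotypes", "genotype_format",
    "sample_table", "stages", "k_range", "replicates", "sweeps", "burnin",
    "alpha", "infer_alpha", "qc_permutations", "sic_pair", "angular_chord",
}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    unknown = set(cfg) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"invalid config keys: {sorted(unknown)}")
    if "simulate" not in cfg and "genotypes" not in cfg:
        raise ValueError("config must name either 'simulate' or 'genotypes'")
    return cfg


def _config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage substream below 2**31."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def run_pipeline(config, out_dir=None) -> Path:
    """Run the configured stages; returns the output directory.

    ``config`` is a dict or a path to a YAML/JSON file.  Missing inputs or
    invalid keys raise before any stage runs.
    """
    if not isinstance(config, dict):
        cfg = load_config(config)
    else:
        cfg = dict(config)
        unknown = set(cfg) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"invalid config keys: {sorted(unknown)}")
        if "simulate" not in cfg and "genotypes" not in cfg:
            raise ValueError("config must name either 'simulate' or 'genotypes'")

    out = Path(out_dir or cfg.get("out_dir", "strmix_out"))
    seed = int(cfg.get("seed", 0))
    stages = list(cfg.get("stages", DEFAULT_STAGES))
    if "genotypes" in cfg and not Path(cfg["genotypes"]).exists():
        raise FileNotFoundError(cfg["genotypes"])
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(cfg),
        "seed": seed,
        "stages": stages,
        "outputs": {},
        "warnings": [],
    }

    def emit(name: str, path: Path):
        manifest["outputs"][name] = str(path.relative_to(out))

    t0 = time.time()
    # --- inputs -----------------------------------------------------------
    if "simulate" in cfg:
        sim_kwargs = dict(cfg["simulate"] or {})
        sim_kwargs.setdefault("seed", _stage_seed(seed, "simulate"))
        if "alleles_per_locus" in sim_kwargs:
            sim_kwargs["alleles_per_locus"] = tuple(sim_kwargs["alleles_per_locus"])
        sim_config = SimConfig(**sim_kwargs)
        matrix, table, truth = simulate_dataset(sim_config)
        io.write_structure(matrix, out / "genotypes.str", table)
        io.write_genepop(matrix, table, out / "genotypes.gen")
        io.write_sample_table(table, out / "samples.tsv")
        truth_blob = {
            "true_Q": truth.true_Q.tolist(),
            "pedigree_class": truth.pedigree_class,
            "mt_clade": truth.mt_clade,
        }
        (out / "truth.json").write_text(json.dumps(truth_blob))
        for name in ("genotypes.str", "genotypes.gen", "samples.tsv", "truth.json"):
            emit(name.split(".")[0] + "_" + name.split(".")[1], out / name)
    else:
        fmt = cfg.get("genotype_format", "structure")
        if fmt == "structure":
            matrix, table = io.read_structure(cfg["genotypes"])
        elif fmt == "genepop":
            matrix, table = io.read_genepop(cfg["genotypes"])
        else:
            raise ValueError(f"unknown genotype_format {fmt!r}")
        if "sample_table" in cfg:
            table = io.read_sample_table(cfg["sample_table"])
    log.info("inputs ready: %d individuals x %d loci (%.1fs)",
             matrix.n_individuals, matrix.n_loci, time.time() - t0)

    # --- QC ---------------------------------------------------------------
    if "qc" in stages:
        t = time.time()
        report = qc.qc_report(
            matrix,
            n_permutations=int(cfg.get("qc_permutations", 2000)),
            seed=_stage_seed(seed, "qc"),
        )
        report.to_csv(out / "qc_report.tsv", sep="\t", index=False)
        emit("qc_report", out / "qc_report.tsv")
        pairs = qc.linkage_matrix(
            matrix,
            n_permutations=int(cfg.get("qc_permutations", 2000)),
            seed=_stage_seed(seed, "linkage"),
        )
        pairs.to_csv(out / "linkage.tsv", sep="\t", index=False)
        emit("linkage", out / "linkage.tsv")
        log.info("qc done (%.1fs)", time.time() - t)

    # --- admixture over a K range ----------------------------------------
    estimates: dict[int, list[admixture.AncestryEstimate]] = {}
    if "admixture" in stages:
        t = time.time()
        k_range = list(cfg.get("k_range", [1, 2, 3, 4]))
        reps = int(cfg.get("replicates", 3))
        rows = []
        for K in k_range:
            estimates[K] = []
            for r in range(reps):
                spec = admixture.AdmixtureModelSpec(
                    K=K,
                    alpha=float(cfg.get("alpha", 1.0)),
                    infer_alpha=bool(cfg.get("infer_alpha", False)),
                    sweeps=int(cfg.get("sweeps", 500)),
                    burnin=int(cfg.get("burnin", 200)),
                    seed=_stage_seed(seed, f"admix:{K}:{r}"),
                )
                est = admixture.gibbs_admixture(matrix, spec)
                if estimates[K]:
                    est = admixture.align_cluster_labels(estimates[K][0], est)
                estimates[K].append(est)
                rows.append({"K": K, "replicate": r, "L_hat": est.L_hat})
        pd.DataFrame(rows).to_csv(out / "L_table.tsv", sep="\t", index=False)
        emit("L_table", out / "L_table.tsv")
        main_k = 2 if 2 in estimates else k_range[0]
        q = pd.DataFrame(
            estimates[main_k][0].Q,
            columns=[f"q_{k + 1}" for k in range(main_k)],
        )
        q.insert(0, "individual_id", estimates[main_k][0].individual_ids)
        locs = table.set_index("individual_id")["locale"]
        q.insert(1, "locale", locs.loc[q["individual_id"]].values)
        q.to_csv(out / "Q_matrix.tsv", sep="\t", index=False)
        emit("Q_matrix", out / "Q_matrix.tsv")
        locale_q = admixture.mean_cluster_by_locale(estimates[main_k][0], table)
        locale_q.to_csv(out / "locale_q.tsv", sep="\t", index=False)
        emit("locale_q", out / "locale_q.tsv")
        log.info("admixture done (%.1fs)", time.time() - t)

    if "deltak" in stages:
        if len(estimates) >= 3:
            L_runs = {K: [e.L_hat for e in v] for K, v in estimates.items()}
            dk = admixture.evanno_delta_k(L_runs)
            dk.to_csv(out / "delta_k.tsv", sep="\t", index=False)
            emit("delta_k", out / "delta_k.tsv")
        else:
            msg = "deltak skipped: insufficient K values (need >= 3)"
            log.warning(msg)
            manifest["warnings"].append(msg)

    # --- ordination and tree ----------------------------------------------
    if "fca" in stages:
        t = time.time()
        coords, inertia = ordination.fca(matrix)
        coords = coords.iloc[:, : min(10, coords.shape[1])].copy()
        coords["locale"] = (
            table.set_index("individual_id").loc[coords.index, "locale"].values
        )
        coords.to_csv(out / "fca_coords.tsv", sep="\t")
        pd.DataFrame(
            {"axis": np.arange(1, len(inertia) + 1), "inertia_pct": inertia}
        ).to_csv(out / "fca_inertia.tsv", sep="\t", index=False)
        emit("fca_coords", out / "fca_coords.tsv")
        emit("fca_inertia", out / "fca_inertia.tsv")
        log.info("fca done (%.1fs)", time.time() - t)

    if "tree" in stages:
        t = time.time()
        labels, D = ordination.chord_distance_matrix(
            matrix, table, angular=bool(cfg.get("angular_chord", False))
        )
        dm = pd.DataFrame(D, index=labels, columns=labels)
        dm.to_csv(out / "chord_distances.tsv", sep="\t")
        emit("chord_distances", out / "chord_distances.tsv")
        if len(labels) >= 3:
            newick = ordination.neighbor_joining(D, labels)
            (out / "locale_tree.nwk").write_text(newick + "\n")
            emit("locale_tree", out / "locale_tree.nwk")
        log.info("tree done (%.1fs)", time.time() - t)

    # --- information content ----------------------------------------------
    if "sic" in stages:
        t = time.time()
        pair = cfg.get("sic_pair")
        t_idx = table.set_index("individual_id")
        if pair:
            side_a, side_b = pair
            labels_map = {
                i: ("A" if t_idx.at[i, "locale"] == side_a else "B")
                for i in matrix.individual_ids
                if t_idx.at[i, "locale"] in (side_a, side_b)
            }
        else:
            labels_map = {
                i: ("forest" if t_idx.at[i, "habitat"] == "forest" else "savanna")
                for i in matrix.individual_ids
            }
        sub = matrix.subset_individuals(list(labels_map))
        freqs, _ = informativeness.population_freqs(sub, labels_map)
        pops = sorted(freqs)
        if len(pops) == 2:
            ranking = informativeness.rank_loci(freqs[pops[0]], freqs[pops[1]])
            ranking.to_csv(out / "sic_ranking.tsv", sep="\t", index=False)
            emit("sic_ranking", out / "sic_ranking.tsv")
        else:
            msg = "sic skipped: need exactly two populations"
            log.warning(msg)
            manifest["warnings"].append(msg)
        log.info("sic done (%.1fs)", time.time() - t)

    # --- mito-nuclear -------------------------------------------------------
    if "mito" in stages:
        if "admixture" in stages and (table["mt_clade"] != "unknown").any():
            locale_q = admixture.mean_cluster_by_locale(estimates[main_k][0], table)
            savanna_col = _savanna_column(estimates[main_k][0], table)
            summaries = mitonuclear.locale_summaries(table, locale_q, savanna_col)
            conc = mitonuclear.concordance_table(summaries)
            conc.to_csv(out / "concordance.tsv", sep="\t", index=False)
            emit("concordance", out / "concordance.tsv")
            try:
                tab, p = mitonuclear.habitat_association(summaries)
                blob = {"table": tab.tolist(), "p_two_tailed": p}
            except ValueError as exc:
                blob = {"error": str(exc)}
                manifest["warnings"].append(f"mito association: {exc}")
            (out / "habitat_association.json").write_text(json.dumps(blob))
            emit("habitat_association", out / "habitat_association.json")
        else:
            msg = "mito skipped: needs admixture stage and mtDNA labels"
            log.warning(msg)
            manifest["warnings"].append(msg)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("pipeline complete in %.1fs -> %s", time.time() - t0, out)
    return out


def _savanna_column(estimate, table: pd.DataFrame) -> str:
    """Name of the Q column tracking savanna-habitat individuals."""
    t = table.set_index("individual_id")
    sav = [
        i for i, iid in enumerate(estimate.individual_ids)
        if t.at[iid, "habitat"] == "savanna"
    ]
    if not sav or estimate.K < 2:
        return "q_1"
    k = int(np.argmax(estimate.Q[sav].mean(axis=0)))
    return f"q_{k + 1}"
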