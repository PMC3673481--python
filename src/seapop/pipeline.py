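"""Configuration-driven pipeline chaining all analysis stages.

A single YAML/dict config drives the six stages

    simulate  — synthetic seascape, sites, environment, genotypes
    disperse  — particle releases on the velocity field
    connect   — connectivity matrix, powering, site aggregation, network
    popgen    — theta, diversity, pairwise FST, MDS
    outliers  — FST-outlier scan against the neutral envelope
    assoc     — Mantel battery and allele-environment associations

Each stage writes its tables (CSV/TSV) and a JSON report into the
output directory; a final ``run.json`` records the seed, config and
package version.  Outputs are deterministic for a fixed seed + config.
"""

from __future__ import annotations

import json

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assoc import mantel, partial_mantel, sam_logistic, sam_to_frame
from .connectivity import (
    aggregate_sites,
    assemble,
    build_network,
    connectivity_to_distance,
    migration_from_connectivity,
    network_to_edgelist,
    power,
)
from .core import PairwiseMatrix
from .demography import DemographyConfig, simulate_genotypes
from .dispersal import ReleaseScheme, run_releases
from .genepop import read_genepop, write_genepop
from .outliers import NeutralSimConfig, calls_to_frame, scan_outliers
from .popgen import allelic_richness, classical_mds, expected_het, pairwise_theta, theta_wc
from .qc import filter_individuals_by_completeness
from .seascape import build_seascape, make_environment, marine_distance_matrix, place_sites

ALL_STAGES = ["simulate", "disperse", "connect", "popgen", "outliers", "assoc"]


class ConfigError(ValueError):
    """Raised for inconsistent or incomplete pipeline configuration."""


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def _validate(config: dict, stages: list[str]) -> None:
    """Fail before any compute when a stage lacks its inputs."""
    have_sim = "simulate" in stages
    if ("disperse" in stages or "connect" in stages) and not have_sim:
        raise ConfigError("disperse/connect stages require the simulate stage")
    if "connect" in stages and "disperse" not in stages:
        raise ConfigError("connect stage requires the disperse stage")
    for s in ("popgen", "outliers", "assoc"):
        if s in stages and not have_sim and "genotypes" not in config:
            raise ConfigError(f"stage {s!r} needs a 'genotypes' input or the simulate stage")
    if "assoc" in stages and not have_sim and "environment" not in config:
        raise ConfigError("assoc stage needs an 'environment' input or the simulate stage")


def run_pipeline(config: dict | str | Path, out_dir, seed: int | None = None) -> dict:
    """Run the configured stages; returns {stage: report path}.

    ``seed`` overrides the config seed.  Stage sub-dicts override the
    defaults of the corresponding modules; see the module docstring for
    the stage names.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0) if seed is None else seed)
    stages = config.get("stages", "all")
    stages = ALL_STAGES if stages in ("all", None) else list(stages)
    unknown = [s for s in stages if s not in ALL_STAGES]
    if unknown:
        raise ConfigError(f"unknown stages: {unknown}")
    _validate(config, stages)

    reports: dict[str, str] = {}
    state: dict = {}

    def report(stage: str, payload: dict) -> None:
        path = out / f"stage_{stage}.json"
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True, default=str)
        reports[stage] = str(path)

    if "simulate" in stages:
        sc = config.get("seascape", {})
        sea, field = build_seascape(
            nx=sc.get("nx", 60),
            ny=sc.get("ny", 40),
            cell_size=sc.get("cell_size", 15.0),
            seed=seed,
            span_days=sc.get("span_days", 40.0),
        )
        placement = place_sites(sea, config.get("sites", {}).get("n_sites", 15), seed=seed + 1)
        env = make_environment(sea, placement, seed=seed + 2)
        env.to_csv(out / "environment.csv")
        state.update(sea=sea, field=field, placement=placement, env=env)
        # genotypes are simulated in this stage unless connect-derived
        # migration is requested (then they wait for the connect stage)
        demo_cfg = config.get("demography", {})
        state["demography"] = demo_cfg
        if not demo_cfg.get("migration_from_connectivity", "connect" in stages):
            dc = DemographyConfig(
                n_demes=len(placement.labels),
                **{k: v for k, v in demo_cfg.items() if k not in ("migration_from_connectivity",)},
            )
            state["table"] = simulate_genotypes(dc, env, seed=seed + 3)
            write_genepop(state["table"], out / "genotypes.gen")
        report(
            "simulate",
            {
                "n_sites": len(placement.labels),
                "n_water_cells": int(sea.water_mask.sum()),
                "n_shallow_cells": int(len(sea.shallow_cells())),
                "seed": seed,
            },
        )
    else:
        if "genotypes" in config:
            state["table"] = read_genepop(config["genotypes"])
        if "environment" in config:
            state["env"] = pd.read_csv(config["environment"], index_col=0)

    if "disperse" in stages:
        rl = config.get("release", {})
        scheme = ReleaseScheme(
            particles_per_cell=rl.get("particles_per_cell", 20),
            releases_per_year=rl.get("releases_per_year", 3),
            n_years=rl.get("n_years", 1),
            duration_days=rl.get("duration_days", 21.0),
            dt_hours=rl.get("dt_hours", 2.0),
            spring_window=tuple(rl.get("spring_window", (0.0, 15.0))),
            year_length_days=rl.get("year_length_days", 365.0),
        )
        cells = state["sea"].shallow_cells()
        traj = run_releases(state["field"], state["sea"], scheme, cells, seed=seed + 4)
        state.update(trajectories=traj, scheme=scheme, cells=cells)
        report(
            "disperse",
            {
                "n_trajectories": int(traj.n),
                "trajectories_per_cell": scheme.trajectories_per_cell,
                "lost_fraction": traj.lost_fraction,
            },
        )

    if "connect" in stages:
        cc = config.get("connectivity", {})
        P1 = assemble(state["trajectories"], state["cells"])
        Pn = power(P1, cc.get("n_generations", 30))
        conn = aggregate_sites(Pn, state["placement"])
        graph = build_network(conn, cc.get("threshold", 1e-20))
        network_to_edgelist(graph, out / "network.tsv")
        dmat = connectivity_to_distance(conn, cc.get("floor", 1e-60))
        dmat.to_csv(out / "connectivity_distance.csv")
        pd.DataFrame(conn.D, index=conn.sites, columns=conn.sites).to_csv(
            out / "site_connectivity_directed.csv"
        )
        state.update(conn=conn, conn_distance=dmat)
        if "table" not in state and "simulate" in stages:
            demo_cfg = dict(state.get("demography", {}))
            demo_cfg.pop("migration_from_connectivity", None)
            m_total = demo_cfg.pop("m_total", 0.135)
            M = migration_from_connectivity(conn, m_total, site_scaling="log")
            dc = DemographyConfig(
                n_demes=len(conn.sites), migration=M, m_total=m_total, **demo_cfg
            )
            state["table"] = simulate_genotypes(dc, state["env"], seed=seed + 3)
            write_genepop(state["table"], out / "genotypes.gen")
        off = conn.S[~np.eye(len(conn.sites), dtype=bool)]
        pos = off[off > 0]
        report(
            "connect",
            {
                "n_directed_pairs": conn.n_directed_pairs,
                "n_edges": graph.number_of_edges(),
                "log10_connectivity_span": float(
                    np.log10(pos.max()) - np.log10(pos.min())
                )
                if len(pos)
                else None,
            },
        )

    if "popgen" in stages:
        table = state["table"]
        pg = config.get("popgen", {})
        table, removal = filter_individuals_by_completeness(
            table, pg.get("min_typed", 0)
        )
        res = theta_wc(table)
        fst = pairwise_theta(table)
        fst.to_csv(out / "pairwise_fst.csv")
        res.per_locus.to_csv(out / "per_locus_theta.tsv", sep="\t", header=["theta"])
        he = expected_het(table)
        ar = allelic_richness(table)
        he.to_csv(out / "expected_het.csv")
        ar.to_csv(out / "allelic_richness.csv")
        coords, eig = classical_mds(fst, k=min(2, fst.n - 1))
        coords.to_csv(out / "mds_coordinates.csv")
        state.update(table=table, fst=fst, theta=res, he=he, ar=ar)
        report(
            "popgen",
            {
                "multilocus_theta": res.multilocus,
                "n_individuals": table.n_individuals,
                "n_removed": len(removal.removed_ids),
                "n_loci_used": int(res.per_locus.notna().sum()),
                "n_pairs": fst.n * (fst.n - 1) // 2,
            },
        )

    if "outliers" in stages:
        table = state["table"]
        oc = config.get("outliers", {})
        sizes = [len(table.site_indices(s)) for s in table.site_labels]
        cfg = NeutralSimConfig(
            n_demes=len(table.site_labels),
            sample_sizes=np.array(sizes),
            n_sims=oc.get("n_sims", 5000),
            mutation_model=oc.get("mutation_model", "IAM"),
            ci_level=oc.get("ci_level", 0.95),
            fdr=oc.get("fdr", 0.05),
            he_bins=oc.get("he_bins", 20),
            seed=seed + 5,
        )
        calls, meta = scan_outliers(table, cfg)
        frame = calls_to_frame(calls)
        frame.to_csv(out / "outlier_calls.tsv", sep="\t", index=False)
        report(
            "outliers",
            {
                "neutral_mean_fst": meta["neutral_mean_fst"],
                "n_significant": int(frame["significant"].sum()),
                "significant_loci": sorted(frame.loc[frame.significant, "locus"]),
            },
        )

    if "assoc" in stages:
        table = state["table"]
        env = state["env"]
        amc = config.get("assoc", {})
        n_perm = amc.get("n_permutations", 999)
        fst = state.get("fst") or pairwise_theta(table)
        battery: list[dict] = []
        if "conn_distance" in state:
            res = mantel(fst, state["conn_distance"], n_perm, seed=seed + 6)
            battery.append({"pair": "fst~conn_distance", "r": res.r, "p": res.p})
        if "sea" in state:
            cells = state["placement"].site_cells
            geo = marine_distance_matrix(state["sea"], cells)
            geo = PairwiseMatrix(
                state["placement"].labels, 0.5 * (geo + geo.T), kind="geo_distance"
            )
            res = mantel(fst, geo, n_perm, seed=seed + 7)
            battery.append({"pair": "fst~geo_distance", "r": res.r, "p": res.p})
            if "conn_distance" in state:
                pres = partial_mantel(fst, state["conn_distance"], geo, n_perm, seed=seed + 8)
                battery.append(
                    {
                        "pair": "fst~conn_distance|geo",
                        "r": pres.r,
                        "p": pres.p,
                    }
                )
        variables = amc.get(
            "variables", ["salinity_april", "temperature_april", "distance_to_entrance"]
        )
        from .assoc import env_distance

        for v in variables:
            res = mantel(fst, env_distance(env, v), n_perm, seed=seed + 9)
            battery.append({"pair": f"fst~{v}", "r": res.r, "p": res.p})
        pd.DataFrame(battery).to_csv(out / "mantel_battery.tsv", sep="\t", index=False)
        sam = sam_logistic(table, env, variables)
        sam_to_frame(sam).to_csv(out / "sam_results.tsv", sep="\t", index=False)
        report(
            "assoc",
            {
                "mantel_tests": len(battery),
                "n_sam_tests": len(sam),
                "n_sam_sig_05": int(sum(r.sig_05 for r in sam)),
            },
        )

    with open(out / "run.json", "w") as fh:
        json.dump(
            {"seed": seed, "stages": stages, "version": __version__, "config": config},
            fh,
            indent=1,
            sort_keys=True,
            default=str,
        )
    reports["run"] = str(out / "run.json")
    return reports
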