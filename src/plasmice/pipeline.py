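"""End-to-end orchestration: build → ionize → simulate → analyze.

The two-step model: a collisional-radiative plasma stage produces
charge-state populations, electron density/temperature and the Debye
length; the molecular-dynamics stage consumes them through the screened
force field.  Observables (RDF, S(q), damage-weighted intensity,
half-times, PADF volumes and peak tracks) are aggregated over several
charge-realization seeds with standard deviations, as single-trajectory
charge placement is stochastic.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time as _time
from pathlib import Path

import numpy as np
import yaml

from . import crystal, ionization, md, observables

__all__ = ["RunConfig", "run_pipeline", "make_fixture", "intensity_vs_time"]


DEFAULT_CONFIG = {
    "pulse": {
        "photon_energy_ev": 8000.0,
        "intensity_w_cm2": 1e18,
        "duration_fs": 50.0,
    },
    "crystal": {
        "replications": [8, 3, 4],
        "lattice_a": crystal.DEFAULT_LATTICE[0],
        "lattice_c": crystal.DEFAULT_LATTICE[1],
        "proton_seed": 0,
    },
    "forcefield": {
        "f_const": 1.0,
        "screening": True,
    },
    "md": {
        "dt_fs": 0.5,
        "n_steps": 100,
        "stride": 10,
        "temperature_k": 265.0,
    },
    "analysis": {
        "r_max": 10.0,
        "rdf_bin": 0.02,
        "q_min": 0.2,
        "q_max": 6.0,
        "q_step": 0.01,
        "half_time_q": [1.66, 2.98, 4.95],
    },
    "seeds": [1, 2, 3, 4, 5],
    "output": "runs/default",
}


@dataclasses.dataclass
class RunConfig:
    """Validated pipeline configuration (units in field names / YAML keys)."""

    data: dict

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        return cls.from_dict(user)

    @classmethod
    def from_dict(cls, user: dict) -> "RunConfig":
        data = json.loads(json.dumps(DEFAULT_CONFIG))
        for section, values in user.items():
            if section not in data:
                raise ValueError(f"unknown config section {section!r}")
            if isinstance(values, dict):
                for k, v in values.items():
                    if k not in data[section]:
                        raise ValueError(f"unknown key {section}.{k}")
                    data[section][k] = v
            else:
                data[section] = values
        cfg = cls(data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        d = self.data
        if d["pulse"]["intensity_w_cm2"] < 0:
            raise ValueError("pulse.intensity_w_cm2 must be >= 0")
        if d["md"]["dt_fs"] <= 0 or d["md"]["dt_fs"] > 0.5:
            raise ValueError("md.dt_fs must be in (0, 0.5]")
        if not d["seeds"]:
            raise ValueError("at least one seed required")

    def __getitem__(self, key):
        return self.data[key]


def intensity_vs_time(traj, plasma, analysis=None):
    """Damage-weighted I(q, t) of a trajectory (Eq. 4/5 pipeline).

    RDFs for all species pairs → Lorch-windowed partial structure factors
    → population-weighted form factors → per-atom intensity.
    """
    a = analysis or DEFAULT_CONFIG["analysis"]
    r_max = min(a["r_max"], float(np.min(traj.box)) / 2.0)
    pairs = [("O", "O"), ("O", "H"), ("H", "H")]
    rdfs = {p: observables.compute_rdf(traj, p, r_max, a["rdf_bin"]) for p in pairs}
    q = np.arange(a["q_min"], a["q_max"], a["q_step"])
    s = {p: observables.partial_structure_factor(r, q)[1] for p, r in rdfs.items()}
    times = rdfs[pairs[0]].times
    table = observables.water_form_factor_table(q)
    if plasma is not None:
        ff = {
            el: np.array(
                [
                    observables.effective_form_factor(
                        table.factors[el], plasma.populations_at(el, t)
                    )
                    for t in times
                ]
            )
            for el in ("O", "H")
        }
    else:
        ff = {el: observables.neutral_form_factor(el, q) for el in ("O", "H")}
    return observables.scattered_intensity(
        q, s, ff, {"O": 1.0 / 3.0, "H": 2.0 / 3.0}, times=times
    ), rdfs


def run_pipeline(config: RunConfig, progress=print) -> dict:
    """Execute the two-step model for every seed and aggregate observables.

    Writes structures, the plasma table, trajectories, tidy observable
    CSVs and a manifest into the configured output directory.  Returns a
    summary dict (also stored as ``manifest.json``).
    """
    out = Path(config["output"])
    out.mkdir(parents=True, exist_ok=True)
    stage = "build"
    t_start = _time.time()
    manifest = {"stages": {}, "seeds": list(config["seeds"])}
    try:
        c = config["crystal"]
        structure = crystal.build_ice_ih(
            tuple(c["replications"]),
            (c["lattice_a"], c["lattice_c"]),
            c["proton_seed"],
        )
        crystal.write_structure(structure, out / "initial.pdb")
        manifest["stages"]["build"] = {
            "n_molecules": structure.n_molecules,
            "wall_s": round(_time.time() - t_start, 2),
        }
        progress(f"[build] {structure.n_molecules} molecules")

        stage = "ionize"
        t0 = _time.time()
        p = config["pulse"]
        pulse = ionization.PulseSpec(
            p["photon_energy_ev"], p["intensity_w_cm2"], p["duration_fs"]
        )
        plasma = ionization.evolve_plasma(pulse, timestep=0.5)
        ionization.write_plasma_table(plasma, out / "plasma.csv")
        manifest["stages"]["ionize"] = {
            "mean_O_charge_end": float(plasma.mean_charge("O")[-1]),
            "lambda_d_end_A": float(plasma.lambda_d[-1]),
            "wall_s": round(_time.time() - t0, 2),
        }
        progress(f"[ionize] Z_O(end)={plasma.mean_charge('O')[-1]:.2f}")

        stage = "simulate"
        t0 = _time.time()
        m = config["md"]
        ffc = config["forcefield"]
        half_times = {}
        rdf_stack = []
        for seed in config["seeds"]:
            traj = md.integrate(
                structure,
                plasma if p["intensity_w_cm2"] > 0 else None,
                dt=m["dt_fs"],
                n_steps=m["n_steps"],
                seed=seed,
                stride=m["stride"],
                f_const=ffc["f_const"],
                screening=ffc["screening"],
                temperature_k=m["temperature_k"],
            )
            md.write_trajectory_xyz(traj, out / f"traj_seed{seed}.xyz")
            md.write_energies_csv(traj, out / f"energies_seed{seed}.csv")
            grid, rdfs = intensity_vs_time(
                traj, plasma if p["intensity_w_cm2"] > 0 else None,
                config["analysis"],
            )
            rdf_stack.append(rdfs[("O", "O")])
            for qstar in config["analysis"]["half_time_q"]:
                iq = int(np.argmin(np.abs(grid.q - qstar)))
                ht = observables.intensity_half_time(
                    grid.times, grid.i_inter[:, iq]
                )
                half_times.setdefault(qstar, []).append(ht)
            progress(f"[simulate] seed {seed} done")

        # aggregate
        rows = []
        for qstar, vals in half_times.items():
            finite = [v for v in vals if np.isfinite(v)]
            rows.append(
                {
                    "q_A^-1": qstar,
                    "half_time_mean_fs": float(np.mean(finite)) if finite else np.inf,
                    "half_time_std_fs": float(np.std(finite)) if finite else np.nan,
                    "n_crossed": len(finite),
                }
            )
        import pandas as pd

        pd.DataFrame(rows).to_csv(out / "half_times.csv", index=False)
        g_mean = np.mean([r.g for r in rdf_stack], axis=0)
        g_std = np.std([r.g for r in rdf_stack], axis=0)
        r0 = rdf_stack[0]
        tidy = []
        for it, t in enumerate(r0.times):
            for ir, rr in enumerate(r0.r):
                tidy.append(
                    {"r_A": rr, "time_fs": t, "g_mean": g_mean[it, ir],
                     "g_std": g_std[it, ir], "pair": "O-O"}
                )
        pd.DataFrame(tidy).to_csv(out / "rdf_oo.csv", index=False)
        manifest["stages"]["simulate"] = {
            "n_seeds": len(config["seeds"]),
            "wall_s": round(_time.time() - t0, 2),
        }

        manifest["config"] = config.data
        manifest["hashes"] = {
            f.name: hashlib.sha256(f.read_bytes()).hexdigest()[:16]
            for f in sorted(out.glob("*.csv"))
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        progress(f"[done] artifacts in {out}")
        return manifest
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err


def make_fixture(name: str) -> crystal.Structure:
    """Small deterministic structures shared across tests and examples."""
    if name == "toy_triangle":
        pos = np.array(
            [[0.0, 0.0, 0.0], [2.0, 0.0, 0.0], [1.0, np.sqrt(3.0), 0.0]]
        )
        pos += 5.0
        return crystal.Structure(
            ["O", "O", "O"], pos, [0, 1, 2], np.empty((0, 2), dtype=int),
            [20.0, 20.0, 20.0],
        )
    if name == "toy_square":
        pos = np.array(
            [[0.0, 0.0, 0.0], [2.0, 0.0, 0.0], [2.0, 2.0, 0.0], [0.0, 2.0, 0.0]]
        )
        pos += 5.0
        return crystal.Structure(
            ["O"] * 4, pos, [0, 1, 2, 3], np.empty((0, 2), dtype=int),
            [20.0, 20.0, 20.0],
        )
    if name == "dimer":
        # two rigid waters, O-O at the ice nearest-neighbour distance
        d = 2.75
        base = crystal.build_ice_ih((1, 1, 1), proton_seed=0)
        # take the first molecule and translate a copy along x
        idx = np.flatnonzero(base.molecule == 0)
        pos1 = base.positions[idx]
        pos = np.vstack([pos1, pos1 + np.array([d, 0.0, 0.0])])
        pos = pos - pos.min(axis=0) + 6.0
        return crystal.Structure(
            list(base.species[idx]) * 2,
            pos,
            [0, 0, 0, 1, 1, 1],
            np.array([[0, 1], [0, 2], [3, 4], [3, 5]]),
            [20.0, 20.0, 20.0],
        )
    if name == "mini_ice":
        return crystal.build_ice_ih((2, 2, 3), proton_seed=11)
    if name == "melt_cell":
        return crystal.build_ice_ih((4, 2, 3), proton_seed=11)
    raise ValueError(
        f"unknown fixture {name!r}; options: toy_triangle, toy_square, "
        "dimer, mini_ice, melt_cell"
    )
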