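"""Packaged demo dataset generation.

Everything is generated programmatically and deterministically from a
seed: the 12-library manifest, the 4-generation barcode map, a small
simulated sequencing campaign, toy assay tables and a 10-frame synthetic
trajectory. Intended for demos, tests and pipeline smoke runs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import demux as dmx
from . import library as lib_mod
from . import simulate as sim
from .structdyn import Trajectory, write_multimodel_pdb


def toy_trajectory(seed: int = 0, n_frames: int = 10) -> Trajectory:
    """Synthetic 10-frame protein+DNA system (not from any real structure).

    Three single-carbon "loop residues" (113-115, poly-Ala stand-ins) drift
    toward a 4-atom DNA strand over the frames, so contact distances and
    H-bond occupancies have non-trivial time structure.
    """
    rng = np.random.default_rng(seed)
    protein0 = np.array([[0.0, 0.0, 0.0], [3.8, 0.0, 0.0], [7.6, 0.0, 0.0]])
    dna0 = np.array([[0.0, 8.0, 0.0], [3.0, 8.5, 0.0], [6.0, 9.0, 0.0], [9.0, 9.5, 0.0]])
    frames = []
    for f in range(n_frames):
        drift = np.array([0.0, -0.4 * f, 0.0])
        jitter = rng.normal(0.0, 0.05, size=(7, 3))
        frames.append(np.vstack([protein0 + drift, dna0]) + jitter)
    return Trajectory(
        coords=np.stack(frames),
        elements=np.array(["C", "C", "C", "P", "N", "O", "C"]),
        atom_names=np.array(["CA", "CA", "CA", "P", "N1", "O2", "C1'"]),
        residue_index=np.array([113, 114, 115, 1, 1, 2, 2]),
        resnames=np.array(["ALA", "ALA", "ALA", "DG", "DG", "DC", "DC"]),
        chain_class=np.array(["protein", "protein", "protein", "dna", "dna", "dna", "dna"]),
    )


def demo_panel_tsv() -> pd.DataFrame:
    """16-substrate XXC panel with a WRC-flavoured preference built in."""
    rows = []
    for x2 in ("A", "mC", "G", "T"):
        for x1 in ("A", "mC", "G", "T"):
            f = 0.10
            if x1 in ("A", "G"):      # purine at -1 (the R of WRC)
                f *= 3.0
            if x2 in ("A", "T"):      # A/T at -2 (the W of WRC)
                f *= 1.5
            rows.append({"x2": x2, "x1": x1, "product_fraction": round(f, 4)})
    return pd.DataFrame(rows)


def make_fixtures(out_dir, seed: int = 0) -> dict[str, Path]:
    """Write the demo dataset; returns a name → path map.

    The read set covers the full 12-library × 4-generation design (48 read
    groups) at modest depth with a fitness map favouring the wild-type
    loop residue of each library's position.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    ref = lib_mod.default_reference()
    panel = lib_mod.build_library_panel(ref)
    paths = {}

    lib_mod.write_manifest(panel, out / "libraries.tsv")
    paths["manifest"] = out / "libraries.tsv"
    lib_mod.write_panel_fasta(ref, panel, out / "references.fasta")
    paths["references"] = out / "references.fasta"

    barcodes = dmx.GenerationBarcodeSet()
    pd.DataFrame(
        {"generation": list(barcodes.barcodes), "barcode": list(barcodes.barcodes.values())}
    ).to_csv(out / "barcodes.tsv", sep="\t", index=False)
    paths["barcodes"] = out / "barcodes.tsv"

    # moderate selection: wild-type-like aromatic/charged preferences
    fitness = sim.FitnessMap.from_aa(
        {aa: float(np.exp(rng.normal(0.0, 0.4))) for aa in "ACDEFGHIKLMNPQRSTVWY"}, stop=0.0
    )
    campaign = sim.CampaignConfig(
        libraries=panel, ref=ref, fitness=fitness,
        initial_depth=3_200, bottleneck=3_200, generations=3,
        reads_per_sample=200, error_rate=7e-4,
        seed=int(rng.integers(0, 2**31)),
    )
    result = sim.run_campaign(campaign)
    result.write_fastq(out / "reads.fastq")
    result.write_truth(out / "truth_population.tsv", out / "truth_reads.tsv")
    paths["reads"] = out / "reads.fastq"
    paths["truth_population"] = out / "truth_population.tsv"
    paths["truth_reads"] = out / "truth_reads.tsv"

    demo_panel_tsv().to_csv(out / "xxc_panel.tsv", sep="\t", index=False)
    paths["xxc_panel"] = out / "xxc_panel.tsv"

    pd.DataFrame(
        {
            "culture": list(range(1, 6)) * 2,
            "label": ["WT"] * 5 + ["mutant"] * 5,
            "resistant": list(rng.poisson(30, 5)) + list(rng.poisson(120, 5)),
            "viable": [10**8] * 10,
        }
    ).to_csv(out / "fluctuation.tsv", sep="\t", index=False)
    paths["fluctuation"] = out / "fluctuation.tsv"

    conc = np.array([12.5, 25, 50, 100, 200, 400])
    rates = 10.0 * conc / (50.0 + conc) * (1 + rng.normal(0, 0.03, conc.size))
    pd.DataFrame({"conc_nM": conc, "rate": np.round(rates, 5)}).to_csv(
        out / "kinetics.tsv", sep="\t", index=False
    )
    paths["kinetics"] = out / "kinetics.tsv"

    write_multimodel_pdb(toy_trajectory(seed), out / "trajectory.pdb")
    paths["trajectory"] = out / "trajectory.pdb"

    manifest = {
        "seed": seed,
        "n_libraries": len(panel),
        "n_generations": campaign.generations + 1,
        "n_read_groups": len(result.reads),
        "files": {k: str(v.name) for k, v in paths.items()},
    }
    (out / "fixtures.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    paths["fixtures_manifest"] = out / "fixtures.json"
    return paths
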