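"""Shared loading helpers for the numbered analysis drivers."""
import json
import sys
from pathlib import Path

from gradenet import io as io_mod

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "results" / "data"
RESULTS = ROOT / "results"


def outdir(name: str) -> Path:
    path = RESULTS / name
    path.mkdir(parents=True, exist_ok=True)
    return path


def load_manifest() -> dict:
    path = DATA / "manifest.json"
    if not path.exists():
        sys.exit("no synthetic bundle found; run analysis/01_simulate.py first")
    with path.open() as fh:
        return json.load(fh)


def load_grade_expression(config: dict, grade: str) -> dict:
    datasets = [f"D{i + 1}" for i in range(config["n_datasets"])]
    return {ds: io_mod.read_expression(DATA / f"expr_{ds}_grade{grade}.tsv")
            for ds in datasets}


def load_networks(grades) -> dict:
    nets = {}
    for grade in grades:
        path = RESULTS / "networks" / f"net_grade{grade}.tsv"
        if not path.exists():
            sys.exit("no grade networks found; run analysis/02_build_networks.py")
        nets[grade] = io_mod.read_edge_list(path, grade=grade)
    return nets
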