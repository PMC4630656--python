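"""Topological portrait of the grade networks.

Degree tables, target/regulator multiplicity, hubs (top 10% by total
degree) with their three-way overlap, largest weak component, and the
cross-grade edge overlap. Outputs under results/topology/.
"""
from _common import outdir, load_manifest, load_networks

from gradenet import io as io_mod
from gradenet import topology


def main() -> None:
    config = load_manifest()["config"]
    grades = config["grades"]
    nets = load_networks(grades)
    out_dir = outdir("topology")

    report = {}
    hub_sets = {}
    for grade, net in nets.items():
        topology.degree_frame(net).to_csv(out_dir / f"degrees_grade{grade}.tsv",
                                          sep="\t", index=False)
        frac_tgt, frac_reg = topology.multiplicity_fractions(net)
        size, frac = topology.largest_weak_component(net)
        hub_sets[grade] = topology.hubs(net)
        report[grade] = {
            "multi_target_pct": 100 * frac_tgt,
            "multi_regulator_pct": 100 * frac_reg,
            "largest_component_size": size,
            "largest_component_fraction": frac,
            "n_hubs": len(hub_sets[grade]),
        }
        print(f"grade {grade}: {100 * frac_tgt:.1f}% of TFs regulate >=2 "
              f"targets, {100 * frac_reg:.1f}% are co-regulated by >=2 TFs; "
              f"largest component {size} TFs ({100 * frac:.1f}%)")

    shared_hubs = set.intersection(*hub_sets.values())
    overlap = topology.edge_overlap(list(nets.values()))
    report["shared_hubs"] = sorted(shared_hubs)
    report["edge_overlap"] = {
        "union_edges": overlap["union_edges"],
        "shared_pct": 100 * overlap["shared_fraction"],
        "grade_specific_pct": {g: 100 * v for g, v in
                               overlap["grade_specific_fraction"].items()},
    }
    print(f"{100 * overlap['shared_fraction']:.2f}% of the "
          f"{overlap['union_edges']} union edges occur in >=2 grades; "
          f"{len(shared_hubs)} hub TFs shared by all three grades")
    io_mod.write_json(report, out_dir / "topology.json")
    print(f"wrote topology report to {out_dir}")


if __name__ == "__main__":
    main()
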