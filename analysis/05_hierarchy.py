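"""Hierarchy-height layering of the grade networks.

Classifies every connected TF as master / intermediate / low-level by
h = (O - I)/(O + I) and tracks level transitions across grades. Outputs
under results/hierarchy/.
"""
from _common import outdir, load_manifest, load_networks

from gradenet import io as io_mod
from gradenet.hierarchy import (assignment_frame, classify_levels,
                                level_proportions, level_transitions)


def main() -> None:
    config = load_manifest()["config"]
    grades = config["grades"]
    nets = load_networks(grades)
    out_dir = outdir("hierarchy")

    assignments = {}
    for grade, net in nets.items():
        a = classify_levels(net)
        assignments[grade] = a
        assignment_frame(a).to_csv(out_dir / f"levels_grade{grade}.tsv",
                                   sep="\t", index=False)
        props = level_proportions(a)
        print(f"grade {grade}: {100 * props['master']:.1f}% master, "
              f"{100 * props['intermediate']:.1f}% intermediate, "
              f"{100 * props['low']:.1f}% low-level "
              f"({len(a)} TFs assigned)")

    trans = level_transitions(assignments)
    print(f"level retention among TFs present in consecutive grades: "
          f"{100 * trans['overall_retention']:.1f}%")
    moved = [t for t in trans["transitions"]
             if t["to_level"] not in ("dropped", t["from_level"])][:5]
    for t in moved:
        print(f"  e.g. {t['tf']}: {t['from_level']} (grade {t['from_grade']}) "
              f"-> {t['to_level']} (grade {t['to_grade']})")
    io_mod.write_json({
        "proportions": {g: level_proportions(a) for g, a in assignments.items()},
        "overall_retention": trans["overall_retention"],
        "retention_by_level": {f"{a}->{b}": v for (a, b), v in
                               trans["retention_by_level"].items()},
    }, out_dir / "hierarchy.json")
    print(f"wrote hierarchy tables to {out_dir}")


if __name__ == "__main__":
    main()
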