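"""Feedforward loops: enumeration, positions and cross-grade conservation.

Enumerates induced FFLs per grade, computes per-TF positional frequencies
(top / middle / bottom), measures how many FFL triples are identically
maintained between adjacent grades, and profiles the motif content of the
edges conserved between adjacent grades. Outputs under results/ffl/.
"""
import argparse

from _common import outdir, load_manifest, load_networks

from gradenet import io as io_mod
from gradenet.errors import UndefinedProfileError
from gradenet.ffl import (conserved_edge_motifs, find_ffls,
                          motif_instance_overlap, position_frequencies,
                          position_frequency_frame)
from gradenet.motifs import classify_enrichment, ffl_class_id


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    config = load_manifest()["config"]
    grades = config["grades"]
    nets = load_networks(grades)
    out_dir = outdir("ffl")

    ffls = {}
    for grade, net in nets.items():
        f = find_ffls(net)
        ffls[grade] = f
        io_mod.write_ffl_list(f, out_dir / f"ffls_grade{grade}.tsv")
        freqs = position_frequencies(f, grade=grade)
        position_frequency_frame(freqs).to_csv(
            out_dir / f"positions_grade{grade}.tsv", sep="\t", index=False)
        print(f"grade {grade}: {len(f)} FFLs over "
              f"{len({t for x in f for t in x.tfs})} TFs")

    triple_sets = {g: {x.tfs for x in f} for g, f in ffls.items()}
    common = set.intersection(*triple_sets.values())
    union = set.union(*triple_sets.values())
    print(f"{100 * len(common) / len(union):.2f}% of all observed FFL "
          f"triples are common to the three grades")

    report = {"common_ffl_pct": 100 * len(common) / len(union)}
    for a, b in zip(grades, grades[1:]):
        overlap = motif_instance_overlap(nets[a], nets[b])
        report[f"overlap_{a}_{b}"] = {
            "maintained_combination_pct": 100 * overlap["combination_fraction"],
            "per_class": overlap["per_class"],
        }
        print(f"grades {a}->{b}: {100 * overlap['combination_fraction']:.1f}% "
              f"of three-TF combinations maintained")
        try:
            prof = conserved_edge_motifs(nets[a], nets[b], n_random=500,
                                         seed=args.seed)
            status = classify_enrichment(prof.normalized_profile)
            i = ffl_class_id() - 1
            print(f"  conserved-edge network: FFL class {status[i]} "
                  f"(z = {prof.z_scores[i]:.1f})")
            io_mod.write_json(prof.to_dict(),
                              out_dir / f"conserved_tsp_{a}_{b}.json")
        except UndefinedProfileError:
            print("  conserved-edge network empty; no profile")
    io_mod.write_json(report, out_dir / "ffl_overlap.json")
    print(f"wrote FFL tables to {out_dir}")


if __name__ == "__main__":
    main()
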