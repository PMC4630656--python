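"""Screen last-grade FFLs for survival association.

Runs the two-stage Cox-weighted risk-score screen on dataset D1 (train/test
split, log-rank at alpha = 0.05 in both halves), validates retained FFLs in
dataset D2 by k-means (k = 2) clustering, runs the reverse direction, and
tests the risk groups against IDH status with Fisher's exact test. Outputs
under results/survival/.
"""
import argparse

from _common import DATA, outdir, load_manifest, load_networks

from gradenet import io as io_mod
from gradenet.ffl import find_ffls
from gradenet.survival import (bidirectional_biomarkers, dichotomize,
                               fisher_idh, retained_ffls, risk_scores,
                               screen_ffls, validate_kmeans)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--alpha", type=float, default=0.05)
    args = ap.parse_args()
    manifest = load_manifest()
    config = manifest["config"]
    last = config["grades"][-1]
    net = load_networks([last])[last]
    out_dir = outdir("survival")

    candidates = find_ffls(net)
    expr = {ds: io_mod.read_expression(DATA / f"expr_{ds}_grade{last}.tsv")
            for ds in ("D1", "D2")}
    surv = {ds: io_mod.read_survival(DATA / f"survival_{ds}.tsv")
            for ds in ("D1", "D2")}

    results = screen_ffls(candidates, expr["D1"], surv["D1"],
                          seed=args.seed, alpha=args.alpha)
    kept = retained_ffls(results)
    print(f"{len(kept)} of {len(results)} grade-{last} FFLs prognostic in D1 "
          f"(log-rank p < {args.alpha} in train and test)")
    planted = manifest.get("prognostic_ffl")
    for r in results:
        if r.retained:
            mark = " (planted)" if planted and list(r.ffl.tfs) == planted else ""
            print(f"  {'-'.join(r.ffl.tfs)}{mark}: p_train = {r.p_train:.2e}, "
                  f"p_test = {r.p_test:.2e}, betas = "
                  f"({', '.join(f'{b:.2f}' for b in r.model.betas)})")
            p_km, _ = validate_kmeans(r.ffl, expr["D2"], surv["D2"],
                                      seed=args.seed)
            groups = dichotomize(risk_scores(r.model, expr["D1"]),
                                 r.model.threshold)
            idh = surv["D1"].set_index("sample_id")["idh_status"]
            p_idh = fisher_idh(groups, idh)
            print(f"    k-means validation in D2: p = {p_km:.2e}; "
                  f"IDH association (Fisher): p = {p_idh:.2f}")

    both = bidirectional_biomarkers(candidates, expr["D1"], surv["D1"],
                                    expr["D2"], surv["D2"], seed=args.seed,
                                    alpha=args.alpha)
    print(f"bidirectional protocol: {len(both['a_to_b'])} FFLs D1->D2, "
          f"{len(both['b_to_a'])} D2->D1, {len(both['final'])} final")

    io_mod.write_json({
        "screened": [{
            "ffl": list(r.ffl.tfs), "betas": list(r.model.betas),
            "threshold": r.model.threshold, "p_train": r.p_train,
            "p_test": r.p_test, "retained": r.retained} for r in results],
        "bidirectional_final": [list(f.tfs) for f in both["final"]],
        "planted_ffl": planted,
    }, out_dir / "screen.json")
    print(f"wrote screening results to {out_dir}")


if __name__ == "__main__":
    main()
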