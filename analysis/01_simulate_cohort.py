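"""Stage 1 — draw the synthetic study cohort.

Generates the default cohort (64 tumours across two latent transcriptomic
subtypes, 15 benign reference samples) and writes the six-file bundle under
results/cohort/.  All later stages read from that bundle.
"""

from pathlib import Path

from mpnstkit.synthetic import CohortConfig, generate_cohort, write_cohort

SEED = 1
OUT = Path("results/cohort")


def main() -> None:
    cfg = CohortConfig(seed=SEED)
    cohort = generate_cohort(cfg)
    manifest = write_cohort(cohort, OUT)
    truth = cohort.truth.samples
    print(f"cohort: {cfg.n_tumours} tumours + {cfg.n_references} references, "
          f"seed {SEED}")
    print(truth["subtype"].value_counts().to_string())
    print(f"triploid tumours: {(truth['ploidy'] == 3).sum()}, "
          f"disproportionate-LOH subgroup: {truth['disproportionate_loh'].sum()}")
    for name, path in manifest.items():
        print(f"  wrote {name}: {path}")


if __name__ == "__main__":
    main()
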