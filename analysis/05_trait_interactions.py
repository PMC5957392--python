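"""Stage 2: how landscape-metric importance shifts with invader traits.

Regresses each metric's stage-1 coefficients (across trait combinations) on
the four invasiveness traits, flags interactions whose 95% credible
intervals exclude zero, and writes one CSV per response under stage2/.
"""

import sys
from pathlib import Path

from invadescape.pipeline import headline_config, run_experiment
from invadescape.simulate import RESPONSE_NAMES

OUT = Path("results/experiment")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0


def main() -> None:
    config = headline_config(OUT, master_seed=SEED)
    config.responses = RESPONSE_NAMES
    result = run_experiment(config, stages=("interactions",), force=True)
    table = result.stage2
    print(f"{len(table)} (response, trait, metric) interaction rows -> "
          f"{OUT / 'stage2'}\n")
    sig = table[table["significant"]]
    counts = sig.groupby(["response", "trait"]).size()
    if len(sig):
        print("significant landscape-trait interactions (CI excludes 0):")
        print(counts.to_string())
        strongest = sig.iloc[sig["phi_mean"].abs().argmax()]
        print(f"\nstrongest interaction: {strongest['trait']} x "
              f"{strongest['metric']} on {strongest['response']} "
              f"(phi = {strongest['phi_mean']:.3g})")
    else:
        print("no interactions cleared the 95% credible-interval bar "
              "at this scale.")


if __name__ == "__main__":
    main()
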