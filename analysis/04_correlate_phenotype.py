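#!/usr/bin/env python
"""Correlate per-individual expression with song-sequence phenotype.

Simulates eight F1 birds whose motif bias varies, links a synthetic
expression level to that bias, scores each bird's song, and computes the
Pearson correlations between expression and the motif / repetition
transition rates — the F1-hybrid individual-variation design for linking
a candidate gene's level to species-biased song structure.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from hybridreg import io, simulate, song

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"
SEED = 40


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)
    rows = []
    for bird in range(8):
        p_motif = bird / 7.0
        cfg = simulate.SongConfig(grammar="mixture", p_motif=p_motif,
                                  noise_sd=0.1, n_syllables=30,
                                  seed=SEED + bird)
        rec = simulate.simulate_songs(cfg)[0]
        ts = song.transition_scores(song.build_ssm(rec.trajectories))
        expr = 10.0 + 5.0 * p_motif + rng.normal(0, 0.5)
        rows.append({"bird": f"F1_{bird + 1}", "expr_level": expr,
                     "motif_pct": ts.motif_pct,
                     "repetition_pct": ts.repetition_pct})
    table = pd.DataFrame(rows).set_index("bird")
    io.write_tsv(table.round(3), OUT / "phenotype_table.tsv")

    corr = song.correlation_table(table[["expr_level"]],
                                  table[["motif_pct", "repetition_pct"]])
    io.write_tsv(corr.round(4), OUT / "phenotype_correlations.tsv",
                 index=False)
    print(corr.round(4).to_string(index=False))
    print("\nexpression tracks the motif bias by construction, so the "
          "motif correlation should be strongly positive and the "
          "repetition correlation negative.")


if __name__ == "__main__":
    main()
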