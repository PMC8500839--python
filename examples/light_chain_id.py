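"""Identify a planted light chain from a side-chain size-class pattern.

Builds a synthetic proteome containing one sequence that matches a density
pattern exactly plus decoy homologs with known numbers of class mismatches,
then scores every candidate and applies the three identification criteria
(MS hit, density match, no better homolog).
"""

from axonarray.lcid import best_window_score, rank_candidates
from axonarray.synthetic import SyntheticProteomeConfig, make_proteome

cfg = SyntheticProteomeConfig(
    pattern_length=18, n_decoys=3, decoy_mismatch_counts=(1, 2, 4), seed=5
)
records, pattern, truth = make_proteome(cfg)
print(f"density pattern ({len(pattern)} positions): {pattern.symbols}")

scores = [best_window_score(r.id, str(r.seq), pattern) for r in records]
for s in scores:
    print(f"  {s.record_id:10s} penalty {s.penalty} at offset {s.offset}")

result = rank_candidates(scores, ms_hits={"target_0"})
print(f"\nstatus: {result.status.value}")
print(f"winner: {result.winner.record_id} (penalty {result.winner.penalty}, "
      f"runner-up penalty {result.runner_up_penalty})")
print("(penalty = residues whose size class contradicts the density;")
print(" the target scores 0 and each decoy scores its planted mismatch count)")
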