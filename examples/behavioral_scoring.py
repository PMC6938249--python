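"""Score assessment response sheets by the study's rules.

Rhyme production gives 1 point per target word (of 12) for which the
child produced at least one correct rhyme -- a child rhyming six times
on two targets and never again scores 2, not 12. The phonemic tasks are
plain correct counts, and composite PA is their sum.
"""

from coartic import composite_pa, score_item_task, score_rhyme

# 12 targets; each inner list = judged correctness of the rhymes offered
rhyme_sheet = [[True] * 6, [True, False, True]] + [[False]] * 10
print("rhyme score (six rhymes on two targets only):", score_rhyme(rhyme_sheet))

onset = score_item_task([1, 1, 1, 0, 1, 0, 0, 1, 0, 0, 0, 0])
synth = score_item_task([1, 1, 0, 1, 1, 0, 0, 0, 1, 0, 0, 0])
print("onset deletion:", onset, "| phoneme synthesis:", synth)
print("composite PA (max 24):", composite_pa(onset, synth))
print("missing sub-score propagates:", composite_pa(onset, None))
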