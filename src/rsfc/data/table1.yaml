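# Printed demographic / behavioral summary inputs of the three-group study
# (BPD n=48, NPC n=39, CPD n=21).  Values are group means/SDs, paired-difference
# summaries (regulation minus passive viewing ratings), and BPD-vs-CPD 2x2
# diagnosis/medication counts.  These are inputs to the summary-statistics
# module; the corresponding test statistics are recomputed, never stored.
one_sample_t:
  behavioral_npc: {mean: 16.67, sd: 41.81, n: 38}
  behavioral_bpd: {mean: 11.90, sd: 31.41, n: 47}
  behavioral_cpd: {mean: 11.74, sd: 28.46, n: 21}
anova:
  age:
    - {n: 48, mean: 30.79, sd: 9.21}
    - {n: 39, mean: 28.67, sd: 10.70}
    - {n: 21, mean: 31.48, sd: 11.80}
  iq:  # one NPC IQ value missing, hence n=38
    - {n: 48, mean: 96.88, sd: 10.08}
    - {n: 38, mean: 100.73, sd: 11.38}
    - {n: 21, mean: 98.45, sd: 9.26}
chisq:  # rows: BPD yes/no, CPD yes/no
  major_depressive_disorder: {a: 42, b: 6, c: 13, d: 8}
  substance_abuse: {a: 21, b: 27, c: 1, d: 20}
  posttraumatic_stress_disorder: {a: 17, b: 31, c: 3, d: 18}
  avoidant_pd: {a: 21, b: 27, c: 15, d: 6}
  paranoid_pd: {a: 14, b: 34, c: 0, d: 21}
  antidepressants: {a: 31, b: 17, c: 8, d: 13}
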