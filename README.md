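# spliceamp

Intron-centric splicing analysis for **targeted long-amplicon RNA-seq**
of a single multi-exon transcript — the kind of design used to monitor
the dystrophin (DMD) muscle isoform, whose 79-exon, ~11.3 kb coding
sequence is amplified as one long-range PCR fragment and sequenced as
spliced long reads at very high junction depth.

The package is for people running knockdown/perturbation screens on such
a transcript who need to ask: *which exons changed their inclusion, by
how much, and in which direction, when a given RNA-binding protein was
depleted?*

## What it computes

From spliced alignments (SAM/BAM) and a gene model (BED12/GFF3):

- **Junction counts** per sample from alignment skip operations, with an
  aligned-anchor rule (default 8 nt) and the novel-junction filter
  (≥ 5 reads in at least one treated replicate; annotated junctions are
  always kept).
- **Intron-centric usage**: psi5(j) = count(j)/Σ counts at j's donor,
  psi3(j) = count(j)/Σ counts at j's acceptor, per sample.
- **Event-level usage**: SJ_ES (exon skipping, mean of psi5/psi3 of the
  skip junction), SJ_Altss (alternative 5′/3′ splice site, the psi index
  at the shared annotated site), SJ_PI (pseudoexon insertion, mean of
  the two novel-junction indices). Events are named in exon-relative
  coordinates (`exon71_skip`, `E77+1619`, `PE1a`, `63x`).
- **Per-exon inclusion**: PSI(e) = (c_up + c_down)/(c_up + c_down + 2·c_skip).
- **Differential calls** per event × knockdown condition:
  ΔSJ = SJ(treated) − SJ(control) and ΔPSI, with a **major** tier
  (|ΔSJ| ≥ 0.05 and disjoint mean ± 1 SD intervals) and a **rare** tier
  (0.01 ≤ |ΔSJ| < 0.05), plus per-protein regulator roles
  (activator / repressor / bidirectional) and a responsive-exon census.
- **Synthetic data**: a seeded generator of isoform mixtures and
  454-style spliced alignments over a deterministic dystrophin-like
  79-exon minus-strand model, with exact ground-truth junction counts,
  true exon PSI and true event usage — so the entire pipeline is
  testable end to end without any external data.

## Worked example

Emulate a screen in which knocking down one protein raises exon-71
skipping by 40 percentage points (i.e. a −0.40 inclusion shift on the
39-bp exon), against a quiescent control (2 treated vs 4 control
replicates, junction depth 1638×):

```python
from spliceamp import study_emulation_preset
from spliceamp.cli import RunConfig, run_pipeline

scenario = study_emulation_preset({"si-QKI": {"exon71_skip": 0.40}}, seed=1)
results = run_pipeline(scenario, RunConfig(out_dir="out", seed=1),
                       use_alignments=False)
calls = results["calls"].set_index("event")
print(calls.loc["exon71_skip",
                ["condition", "mean_sj_treated", "mean_sj_control",
                 "delta_sj", "delta_psi", "tier"]])
```

prints (seed 1):

```
condition            si-QKI
mean_sj_treated    0.418082
mean_sj_control    0.027617
delta_sj           0.390465
delta_psi          -0.39046
tier                  major
```

and `results["roles"]` classifies `si-QKI` as an **activator** (its
depletion lowered inclusion). Read as: in the knockdown, 41.8% of
junction reads at the exon-71 flanks support skipping versus 2.8% in
control; exon-71 inclusion dropped by ~0.39 — the injected −0.40 shift,
recovered within sampling noise.

The same pipeline runs from the shell, either on simulated reads or on
your own alignments:

```bash
spliceamp run-all --out out --seed 1                 # preset scenario, SAM reads
spliceamp quantify --model model.bed --samples samples.tsv --control si-ctrl --out out
spliceamp diff --usage out/usage.tsv --samples samples.tsv --control si-ctrl --out out
```

`samples.tsv` maps each sample to a condition and (for `quantify`) an
alignment path. All outputs are TSV with stable columns.

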