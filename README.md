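# ribochase

Inference of RNA decay kinetics and premature transcription termination
from rifampicin-chase RT-qPCR data and steady-state transcript levels,
with an RNase E cleavage-signature scanner.

## The problem

In bacteria such as the cyanobacterium *Synechocystis*, the gene
encoding RNase E (*rne*) carries an unusually long 5′ UTR. Its
steady-state level is far higher than that of the downstream coding
region, and the two segments decay at different rates. Two mechanisms
can produce such a pattern: differential degradation, or premature
transcription termination within the UTR so that only a fraction of
initiating RNA polymerases ever transcribe the ORF. Separating the two
requires combining *decay* measurements (rifampicin chase: block
initiation at t = 0, follow relative abundance by RT-qPCR) with
*steady-state* measurements (transcript intensities).

`ribochase` implements that inference chain for anyone analysing
chase/qPCR experiments of this design:

1. **quantify** — comparative-Ct (ΔΔCt) conversion of raw Ct tables to
   relative abundances: rq = 2^(−ΔΔCt), technical replicates averaged
   on the Ct scale, biological series kept separate.
2. **decay** — pooled nonlinear least-squares fit of
   N(t) = N₀·e^(−λt) across regions × biological replicates per
   compartment; half-life t½ = ln2/λ; nonparametric series-level
   bootstrap 95% intervals.
3. **model** — the steady-state calculus. With Int = α/λ at steady
   state, the synthesis-rate ratio of two species is

       FCsynt(i,j) = αᵢ/αⱼ = (Intᵢ/Intⱼ) · (λᵢ/λⱼ)

   Under a single promoter, FCsynt(UTR, ORF) = 1/(1−f), so the fraction
   of polymerases terminating before the ORF is **f = 1 − 1/FCsynt**.
4. **sites** — scan RNA for the RNase E cleavage signature (U at +2 and
   A at −3/−4 of the scissile bond), find U-tracts, and cluster mapped
   3′-end positions into regions.
5. **simulate** — a seeded generative model of the whole experiment
   (promoter → termination → first-order decay → Ct-scale readout with
   Gaussian cycle noise) that produces every input the pipeline
   consumes.

## Worked example

`examples/02_synthesis_table.py` reconstructs the synthesis-rate table
from measured fold changes (mock UTR/ORF intensity FC 11, decay FC 2.2;
UV UTR/ORF intensity FC 6.5 with half-lives 17.1/7.5 min; UTR UV/mock
intensity FC 2.52 with half-lives 17.1 vs 3.1 min):

```
                      mock UTR/ORF UV UTR/ORF UTR UV/mock
FC of intensity               11.0        6.5         2.5
FC of decay constant           2.2       0.44        0.18
FC of synthesis rate          24.2        2.9        0.46
Termination after UTR        95.9%      64.9%          NA

UTR stabilisation UV vs mock: 5.5 fold
transcription-rate reduction under UV: 2.2 fold
full-length read-through (mock): 4.1 %
```

Reading: under mock conditions the UTR is synthesised 24.2× faster than
the ORF, so 95.9% of initiating polymerases terminate within the UTR
and only 4.1% produce full-length mRNA. Under UV the terminating
fraction drops to ~65% while overall initiation falls ~2.2-fold — the
rise in full-length message comes from relieved termination, not faster
transcription.

`examples/01_simulate_and_fit.py` closes the loop on simulated data
(truth: 3.1 and 7.2 min):

```
simulated 180 qPCR wells (36 reference)
ORF: half-life 6.72 min (95% CI 6.07-7.43, lambda 0.1032 /min, 24 points)
UTR: half-life 3.06 min (95% CI 2.87-3.25, lambda 0.2268 /min, 24 points)
```

The other examples scan a synthetic RNA for cleavage signatures
(`03_site_scan.py`) and run the full simulate → quantify → fit → model
chain with provenance sidecars (`04_full_pipeline.py`).

A thin CLI mirrors the stages:

```sh
ribochase simulate --seed 42 --out qpcr.csv
ribochase quantify --in qpcr.csv --out rq.csv
ribochase fit --in rq.csv --out fits.csv
ribochase model --fc-int-mock 11 --fc-decay-mock 2.2 \
    --fc-int-uv 6.5 --uv-utr-t12 17.1 --uv-orf-t12 7.5 \
    --fc-int-utr-uvmock 2.52 --mock-utr-t12 3.1
ribochase scan --fasta utr.fasta --out-bed sites.bed
ribochase cluster --positions ends.txt
ribochase run --seed 3 --out-dir out/
```

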