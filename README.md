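# apecomm

Bayesian cue integration and Rational Speech Act (RSA) pragmatics for
great-ape communicative interactions.

Great apes signal multimodally: a manual gesture is produced together with
a facial expression, in a social context, toward a higher- or lower-ranking
individual. `apecomm` models the receiver of such an utterance as a
Bayesian observer who integrates all four cues into a posterior over the
sender's binary intention — *affiliative* versus *avoidant* — and compares
that posterior against coded interaction tables in which the receiver's
reaction stands in for the interpreted intention. A one-level RSA extension
models pragmatic amplification of vague pointing gestures in object-choice
tasks. The package is for computational ethologists and pragmatics
researchers who want to fit, simulate, and stress-test these models without
access to the original field recordings.

## The model

Each cue carries a *soft semantics*: a weight θ ∈ [0, 1] read as the
unnormalized multiplicative weight of the avoidant intention (1 − θ for the
affiliative one; θ = 0.5 is uninformative). The posterior over the
intention *i* given utterance *u* = (*g*, *f*) in setting (*c*, *s*) is

    P(i | u) ∝ P(u | i) · P(i)
    P(u | i) = L(g, i | θ_g) · L(f, i | θ_f)
    P(i)     = P(i | c, s) = ρ_c · ρ_s

Equivalently, the avoidant log-odds are additive:
logit P(avoidant | u) = Σ logit θ over the four active cues.

The RSA layer stacks one level of recursion on a literal receiver:

    PR0(i | u) ∝ L(u, i | θ_u)          (literal receiver)
    PS1(u | i) ∝ PR0(i | u)^α           (pragmatic sender, rationality α)
    PR1(i | u) ∝ PS1(u | i) · P(i)      (pragmatic receiver)

With a vague point (θ_u = 0.53) the literal receiver picks the target at
0.53, while the pragmatic receiver amplifies it — to ≈ 0.65 at α = 5 and
≈ 0.77 at α = 10.

## Worked example

```python
import apecomm as ac

params = ac.default_parameters()          # reference cue weights
post = ac.infer_intention(
    ac.Utterance("stretched_arm", "neutral"),
    ac.SocialSetting("negative", "subordinate_sender"),
    params,
)
print(f"p_avoidant = {post.p_avoidant:.4f}")

curve = ac.amplification_curve(ac.symmetric_point_scenario(0.53), [1, 5, 10])
print(curve)
```

prints

```
p_avoidant = 0.8876
   alpha  p_target
0    1.0  0.530000
1    5.0  0.645821
2   10.0  0.768781
```

A stretched-arm gesture (weakly avoidant, θ = 0.53) with a neutral face in
a negative context from a subordinate sender yields an 89% avoidant
posterior — the prior cues (ρ_c = 0.7, ρ_s = 0.75) do most of the work.
The second block is the amplification curve: the same 0.53-vague point is
interpreted at 0.53 by a literal receiver (α = 1 with a uniform prior is
equivalent) but at 0.77 by a pragmatic receiver who assumes an α = 10
informative sender.

The same pipeline is available from the shell:

```bash
apecomm grid --out grid.csv                      # 24-cell prediction grid
apecomm simulate --n 10000 --seed 1 --out data.csv
apecomm evaluate --data data.csv --seed 1 --out eval/
apecomm fit --data data.csv --seed 1 --out fit.json
apecomm rsa --theta-u 0.53 --alpha 1,5,10 --out rsa/
```

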