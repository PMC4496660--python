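# semfood

Ontology-driven dietary decision support: given a food ontology, a
consumer's intolerance list and a product's ingredient list, `semfood`
scores how risky the product is for that consumer and renders a
red/yellow/green verdict, plus forward-chained allergy-risk facts.

It is aimed at health-informatics developers building label-scanning or
shelf-kiosk tools, where the same substance appears on packaging under
trade names, chemical names or E-numbers ("Vitamin C", "Ascorbic Acid",
"E300") and purely syntactic matching misses real risks.

## The method

**Semantic enhancement.** The consumer's raw intolerance terms are first
expanded into the enhanced list *C* through the ontology: synonym edges to
their full closure, group membership and direct is-a parents one hop each.

**Concept matchmaking.** Each consumer concept *C_i* is compared with each
product ingredient concept *P_j* and assigned one of four degrees:

| relation | degree | meaning |
|---|---|---|
| Exact | 1.00 | identical or synonym-equivalent concepts |
| Plugin | 0.75 | hierarchy-related, stronger direction |
| Subsume | 0.50 | hierarchy-related, weaker direction (incl. siblings) |
| Dissimilar | 0.00 | no connection |

Hierarchy links are weighted: every direct subclass edge of a parent with
*n* children carries weight 1/*n* (unless the ontology developer scored it
explicitly), and the weight of a chain is the product of its edge weights,
`d_weight(A,Z) = d_weight(A,B) * ... * d_weight(Y,Z)`, with `distance`
the chain's edge count.

**Greedy matching and aggregation.** A greedy pass over *C* pairs each
concept with the highest-degree remaining ingredient. With *m* the summed
degrees and *l* the number of matched (non-Dissimilar) pairs, a modified
Jaro–Winkler factor is computed:

    d_j = (m/n_C + m/n_P) / 2
    d_w = d_j + l * k * (1 - d_j),      k = 0.1

and the aggregate intolerance score and integer percentage are

    IntoleranceScore(C, P) = [ Σ_i degree_i * weight_i / distance_i ] / ((n_C/n_P) * d_w)
    percentage             = floor(score * 100 / max(n_C, n_P))

**Verdict.** RED if any pair is Exact, YELLOW if only Plugin/Subsume pairs
exist, GREEN otherwise. Independently, DL-safe SWRL-style rules
(`Consumer(?c), Has_Allergy(?c, Lactose_Allergy), ... ->
HAS_LACTOSE_RISK(?c, Aluminium_Silicate)`) forward-chain over the asserted
facts; rule concept arguments are expanded through the matchmaker so a
product declaring "Kaolin" still triggers an "Aluminium Silicate" rule.

Because published descriptions of the Plugin/Subsume direction conflict,
both conventions are implemented (`example`, the default, reproduces the
reference worked scores; `definition` follows the prose definitions). See
`docs/methods.md`.

## Worked example

The packaged worked example ships a small vitamin/alginate ontology, a
consumer intolerant to D-Isoascorbic Acid, Algin and Vitamin B3, and two
products:

```sh
semfood fixtures --out fx
semfood score --ontology fx/ontology.yaml --consumer fx/consumer.yaml \
              --product fx/product2.yaml
```

prints

```
verdict: RED   intolerance 56%   score 1.700
m=2.25  l=3  d_j=0.7500  d_w=0.8250
ingredients: Ascorbyl Palmitate, Niacin, Sodium Alginate
pairs:
  D-Isoascorbic Acid       Ascorbyl Palmitate       Subsume    term=0.0278
  Algin                    Sodium Alginate          Plugin     term=0.3750
  Vitamin B3               Niacin                   Exact      term=1.0000
...
```

and exits with status 2 (RED) for scripting. Reading the numbers: the
sibling pair contributes 0.5·(1/3·1/3)/2 ≈ 0.028, the superclass pair
0.75·0.5/1 = 0.375 and the synonym pair 1·1/1 = 1; with m = 2.25 over
three concepts per list, d_j = 0.75 and d_w = 0.825, giving score
(0.028+0.375+1)/0.825 ≈ 1.700 and percentage ⌊1.700·100/3⌋ = 56. The
Exact synonym hit (Vitamin B3 ↔ Niacin) alone forces the RED verdict.
Product 1 scores 33% with no Exact pair — YELLOW. The same evaluation is
available from Python:

```python
from semfood import worked_example, evaluate, MatchConfig

graph, consumer, p1, p2 = worked_example()
result = evaluate(graph, consumer, p2, MatchConfig(convention="example"))
print(result.percentage)   # 56
```

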