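# rorscreen

Disproportionality screening of spontaneous adverse-event reports:
reporting odds ratios (RORs) with exact 2×2 inference, covariate-adjusted
logistic RORs, and a synthetic reporting-system generator with planted ground
truth.

## Who this is for

Pharmacovigilance analysts and methods researchers working with
spontaneous-reporting-system (SRS) databases in the JADER dialect — three
linked delimited tables (demographics; drugs per case with a *suspected /
interaction / concomitant* role; reactions per case as preferred terms). The
package was built around the canonical antipsychotic movement-disorder
question — do first- and second-generation antipsychotics (FGAs, SGAs) show
reporting signals for tardive dyskinesia (TD) and extrapyramidal symptoms
(EPS)? — but the curation cascade, screen and generator are configuration-
driven and reusable.

## The statistic

For an ADR of interest versus all other (non-movement) ADRs, and a drug group
of interest versus reference drugs, the screen forms the 2×2 table

```
                     ADR of interest   other ADR
drug of interest            a              b
reference drugs             c              d
```

and reports the cross-product ROR = (a·d)/(b·c). Inference conditions on both
margins: cell *a* follows Fisher's noncentral hypergeometric law with odds
parameter ψ, giving the exact two-sided p (minimum-likelihood rule) and exact
conditional (Cornfield) 95% limits by inverting Pr(A ≥ a | ψ) = α/2 and
Pr(A ≤ a | ψ) = α/2. A lower limit above 1 flags the drug of interest; an
upper limit below 1 flags the reference. Adjusted RORs come from a logistic
model with age (≥60), sex, report period and concomitant-use covariates, with
explicit separation handling (0.00–Inf rows instead of spurious estimates).

Curation follows standard SRS practice: (case, ADR, drug) triple
deduplication, suspected-role filtering, nonspecific-term and pediatric
exclusions, clozapine-exposure exclusion for movement-disorder cases, and
competing-case removal per ADR of interest. Every stage is flow-accounted
(input = excluded + retained, asserted).

See `docs/methods.md` for the full model description and design choices.

## Worked example

```python
from rorscreen import (
    curate, default_screen_specs, run_screen, generate, paper_shaped_scenario,
)
from rorscreen.disproportionality import format_screen_table

cfg = paper_shaped_scenario(n_reports=20_000, seed=13)   # planted FGA > SGA effects
db = generate(cfg)
classes = cfg.class_table()
sets, flow = curate(db.cases(), classes=classes)

screen = run_screen(sets, default_screen_specs(sorted(sets)), classes)
td = screen[screen.adr == "tardive dyskinesia"]
print(format_screen_table(td).to_string(index=False))
```

prints (abridged):

```
               adr  drug_group          reference   a    b   c     d   ROR     95% CI       p           signal
tardive dyskinesia        FGAs Non-antipsychotics 172  883 251 13492 10.47 8.47-12.92 < 0.001 drug_of_interest
tardive dyskinesia  SGAs total Non-antipsychotics 167 2013 251 13492  4.46  3.62-5.48 < 0.001 drug_of_interest
tardive dyskinesia  SGAs total               FGAs 167 2013 172   883  0.43  0.34-0.54 < 0.001        reference
```

Reading it: 172 deduplicated TD cases name an FGA as suspected drug against
883 FGA cases with only non-movement reactions; the odds contrast against the
non-antipsychotic reference gives ROR 10.5 with an exact 95% CI excluding 1 —
a drug-of-interest signal, driven by the planted FGA multiplier. The SGA row
recovers its (smaller) planted effect, and the SGA-vs-FGA contrast flags the
*reference* (FGAs), reflecting the planted FGA > SGA ordering.

The same screen is available from a shell:

```
ror-screen simulate --n 20000 --seed 13 --out data/
ror-screen curate   --data data/ --out out/
ror-screen screen   --data data/ --out out/
ror-screen report   --data data/ --screen-csv out/screen.csv --out out/
# or all four at once:
ror-screen run-all --out out/
```

producing `screen.csv` (full precision), `screen_formatted.csv` (display
rounding), `flow.json` (case-selection accounting), demographic tables and
log-scale forest plots (SVG).

To reproduce a *published* screen whose 2×2 cell counts are available, feed
the cells directly — no case-level data needed:

```python
import pandas as pd
from rorscreen import screen_from_cells
cells = pd.read_csv("published_cells.csv")     # columns a, b, c, d (+ labels)
print(screen_from_cells(cells))
```

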