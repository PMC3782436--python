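# seasonfire

Path analysis of how the El Niño–Southern Oscillation (ENSO) shapes wet/dry
seasonality and, through it, a subtropical wildfire regime. The package is a
tested re-implementation of that analysis chain for a south-central Florida
fire-maintained landscape: it characterizes seasons from daily rainfall with
cumulative rainfall anomalies (CRAs), attaches a season-weighted Niño 3.4
index, and fits linear-Gaussian structural equation models (SEMs) — including
an exhaustive BCC-ranked specification search — to descriptor tables of the
kind that study produced. Because the original 58-year rainfall and 30-year
fire records are not public, a first-class synthetic-data module generates
all inputs with known ground truth.

Intended users: ecologists and climate/fire analysts who want CRA season
descriptors and observed-variable path models in one pipeline, and
methodologists who want a small, transparent, fully tested SEM engine.

## The models

**Season descriptors.** The CRA is the running sum of daily rainfall minus a
constant reference rate (the long-term daily mean). While rainfall runs below
the reference the CRA falls; above it, it rises. Per year, the wet-season
onset is the day after the CRA minimum inside a March–July search window and
cessation is the day of the CRA maximum inside an August–December window; the
dry season is the complement. Descriptors per season-year: onset, cessation,
inclusive duration (May 21 → Oct 1 counts 134 days), rainfall (cm), and
*trend consistency* — the R² of a straight line fit to the CRA within the
season, high when drying/moistening proceeds uninterrupted. The seasonal
Niño 3.4 value is the mean of monthly values with partial months weighted by
the number of season days they contain.

**SEM engine.** A path model is a recursive system of regressions among
observed variables. With coefficient matrix **A** and exogenous/error
(co)variance matrix **Ω**, the implied covariance is
Σ(θ) = (I−A)⁻¹ Ω (I−A)⁻ᵀ. Fitting minimizes the Wishart ML discrepancy
F(θ) = ln|Σ| + tr(SΣ⁻¹) − ln|S| − p, giving χ² = (n−1)F at the optimum with
df = p(p+1)/2 − q. Coefficients are reported standardized (SD units), each
endogenous variable gets R² = 1 − error variance / implied variance, and
effects decompose as direct (A), indirect ((I−A)⁻¹ − I − A, i.e. summed
path products), and total. Model selection uses the Browne–Cudeck criterion
BCC = χ² + 2q(n−1)/(n−p−2), a slightly stronger complexity penalty than AIC;
the specification search fits **every** subset of a saturated framework's
optional edges and ranks by ascending BCC.

## Worked example

Fit the best dry-season structure (free coefficients) to a 58-year synthetic
descriptor table drawn from the catalog's fitted model:

```python
from seasonfire import fit_ml, sample_covariance, PathModel, Edge
from seasonfire.catalog import load_entry
from seasonfire.simulate import sample_from_path_model

entry = load_entry("dry_best")
skeleton = PathModel(entry.model.variables,
                     [Edge(e.source, e.target) for e in entry.model.edges])
data = sample_from_path_model(entry, 58, seed=4)
fit = fit_ml(sample_covariance(data), skeleton, 58)
print(fit.summary().to_string(index=False))
print(f"chisq={fit.chisq:.2f} df={fit.df} p={fit.pvalue:.2f} BCC={fit.bcc:.1f}")
```

prints

```
              edge  estimate       se            p  standardized   tier
   onset->duration -0.658458 0.085783 1.642661e-14     -0.712937  thick
duration->rainfall  0.375237 0.090307 3.250738e-05      0.380165  thick
    nino->rainfall  0.596533 0.088489 1.569451e-11      0.616780  thick
      rainfall->tc -0.719116 0.099661 5.368503e-13     -0.674907  thick
      duration->tc  0.603673 0.077560 7.064384e-15      0.574001  thick
          nino->tc -0.259209 0.089261 3.684867e-03     -0.251530 medium
chisq=0.43 df=4 p=0.98 BCC=25.0
```

Each row is one arrow of the path diagram: the raw partial regression
coefficient, its standard error and two-sided z-test p, the standardized
coefficient (SD units, comparable across arrows), and the line-weight tier
used in the diagrams (thick p ≤ 0.001 … dashed non-significant). At n = 58
the standardized estimates sit close to the generating values (e.g.
onset→duration −0.71 vs −0.69 generating), and χ² = 0.43 on 4 df (p = 0.98)
says the structure reproduces the sample covariance well.

Effect decomposition of the preferred wildfire model — ENSO suppresses area
burned only indirectly, by wetting the dry season:

```sh
$ seasonfire effects --model fire_second_best
nino     area        0.00   -0.3009 -0.3009   # 0.59 × −0.51
tc_wet   area        0.00   -0.4437 -0.4437   # two routes, −0.27 + −0.18
rain_dry area       -0.51    0.0000 -0.5100
...
```

The full pipeline (simulate → seasons → transforms → fits → searches →
effect tables) runs from one YAML config: `seasonfire pipeline config.yaml`.

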