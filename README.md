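# mospec

Spreadsheet-specified mixed algebraic/ODE models: validation, simulation,
multi-dialect code generation and automatic LaTeX model reports.

Many modelling groups — especially interdisciplinary biomedical teams — keep
the authoritative definition of an ODE model not in code but in a structured
document that every collaborator can read and edit. `mospec` implements that
workflow: a model lives in an 11-sheet spreadsheet workbook (the **MoSpec**
format, readable and writable as `.ods` or `.xlsx`), and the package acts as
the **Autocoder** that turns it into everything else — a validated in-memory
model, numerical trajectories, runnable source packages in several
programming dialects, and a LaTeX **Companion** document for verification
and publication.

## The model class

A model is a mixed algebraic/differential system over named quantities:

- **State variables** `x_i` defined differentially,
  `dx_i/dt = f_i(x, a, p, t)`, each with an initial condition;
- **Algebraic variables** `a_j = g_j(x, a, p, t)` given in closed form and
  evaluated (in dependency order) at every time point;
- **Free parameters** `p` with reference values, overridable by named
  *configurations* (scenario parameter vectors; `Default` always exists);
- **Determined parameters** computed once, before integration, as functions
  of other parameters;
- **Constraints**: predicates over parameters that must hold before
  simulation, each carrying a numeric error code reported on violation.

All defining formulas are written in one small pseudocode language (infix
arithmetic with `^`, comparisons, `and`/`or`/`not`, builtins such as `Exp`,
`Ln`, `Min`, `Step`, `RandUnif()`, a conditional `If(cond, then, else)` and
the time symbol `t`). The integrator is the classical **fixed-step
fourth-order Runge–Kutta** scheme, with the algebraic layer re-evaluated at
every stage point.

Generated packages (Python — the host dialect — plus R and Julia) contain
the same routines under the same names in each language and embed the same
integrator, so every implementation of a model computes the same
trajectories; the host-dialect output reproduces the in-process engine to
machine precision ("twins" agreement). Workbook sheets 7–10 let a model
override how pseudocode builtins are spelled per dialect (e.g.
`RandUnif()` → `runif()`).

## Worked example

Three example models ship with the package: `TwoLovers` (a Rinaldi-style
linear model of mutual attraction), `SEIR` (a single-node epidemic model
with a conserved total population) and `ConstrainedToy` (one state with a
step forcing, exercising every sheet). From a shell:

```sh
$ mospec fixture TwoLovers --out TwoLovers.ods
$ mospec validate TwoLovers.ods
TwoLovers.MoSpec V02.04.03: valid
$ mospec simulate TwoLovers.ods --config Decoupled --t0 0 --t1 1 --step 0.01 --out tl.csv
wrote tl.csv (101 points); terminal: R=0.367879, J=0.367879, TotalAffection=0.735759
```

The `Decoupled` configuration sets the cross-coupling coefficients to zero
and both self-terms to −1, so each state decays as `e^(−t)`: the terminal
value 0.367879 is `e^(−1)`, and `TotalAffection` (an algebraic variable,
`R + J`) is twice that. The workbook's version line (`V02.04.03`) encodes
model version, implementation sub-version and document edition as a
zero-padded triple.

Code generation and the report:

```sh
$ mospec generate TwoLovers.ods --out gen
wrote python package (5 files) under gen
wrote r package (5 files) under gen
wrote julia package (5 files) under gen
wrote TwoLovers.modpars.dat and .vars.dat
$ (cd gen/python && python TwoLoversAutoTester.py)
wrote TwoLovers_trajectory.csv (2001 points)
$ mospec companion TwoLovers.ods --out doc
wrote Companion main file plus 4 fragments to doc
```

Each generated folder is self-contained: `<Project>AutoTester` simulates
the `Default` configuration over the workbook's time grid, writes a
trajectory CSV and plots the variable time courses. The Companion sources
pair every equation's mathematical form with its verbatim computational
definition — the verbatim text is string-equal to what the code generator
emits, which is what makes the document a verification surface for the
code. `mospec plot` overlays up to four configurations (black, blue, green,
red) across eight compass quadrants, with observed data points from a CSV
superimposed; `--scan parameter=lo:hi:n` sweeps one free parameter instead.

Other commands: `mospec template <project> <path>` writes a blank workbook
with all eleven obligatory sheets and yellow fill-in cells.

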