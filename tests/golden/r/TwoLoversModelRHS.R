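# TwoLoversModelRHS.R - model right-hand side
# Generated by the mospec Autocoder from TwoLovers.MoSpec V02.04.03
# Do not edit: regenerate from the model workbook instead.

STATE_NAMES <- base::c("R", "J")
ALGEBRAIC_NAMES <- base::c("TotalAffection")

AlgebraicValues <- function(t, y, pars) {
  a <- pars[["a"]]
  b <- pars[["b"]]
  c <- pars[["c"]]
  d <- pars[["d"]]
  R0 <- pars[["R0"]]
  J0 <- pars[["J0"]]
  CouplingGain <- pars[["CouplingGain"]]
  R <- y[[1]]
  J <- y[[2]]
  TotalAffection <- R + J
  base::c(TotalAffection)
}

ModelRHS <- function(t, y, pars) {
  a <- pars[["a"]]
  b <- pars[["b"]]
  c <- pars[["c"]]
  d <- pars[["d"]]
  R0 <- pars[["R0"]]
  J0 <- pars[["J0"]]
  CouplingGain <- pars[["CouplingGain"]]
  R <- y[[1]]
  J <- y[[2]]
  TotalAffection <- R + J
  d_R <- a * R + b * J
  d_J <- c * R + d * J
  base::c(d_R, d_J)
}

InitialConditions <- function(pars, t) {
  a <- pars[["a"]]
  b <- pars[["b"]]
  c <- pars[["c"]]
  d <- pars[["d"]]
  R0 <- pars[["R0"]]
  J0 <- pars[["J0"]]
  CouplingGain <- pars[["CouplingGain"]]
  base::c(R0, J0)
}

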