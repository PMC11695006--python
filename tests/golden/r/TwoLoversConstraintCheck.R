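# TwoLoversConstraintCheck.R - parameter constraint checks
# Generated by the mospec Autocoder from TwoLovers.MoSpec V02.04.03
# Do not edit: regenerate from the model workbook instead.

CheckConstraints <- function(pars) {
  a <- pars[["a"]]
  b <- pars[["b"]]
  c <- pars[["c"]]
  d <- pars[["d"]]
  R0 <- pars[["R0"]]
  J0 <- pars[["J0"]]
  CouplingGain <- pars[["CouplingGain"]]
  violated <- base::c()
  violated
}

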