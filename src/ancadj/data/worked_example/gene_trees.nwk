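(((xA1[&&NHX:S=A:Ev=Extant:ts=3],xA2[&&NHX:S=A:Ev=Extant:ts=3])xdup[&&NHX:S=A:Ev=Dup:ts=2],(xB[&&NHX:S=B:Ev=Extant:ts=3],(xC[&&NHX:S=C:Ev=Extant:ts=3])xtr[&&NHX:S=C:Ev=Trans:ts=2])xso[&&NHX:S=B:Ev=SpecOut:ts=2])xe[&&NHX:S=e:Ev=Spec:ts=1],(xlossC[&&NHX:S=C:Ev=Loss:ts=2],xD[&&NHX:S=D:Ev=Extant:ts=3])xf[&&NHX:S=f:Ev=Spec:ts=2])xr[&&NHX:S=r:Ev=Spec:ts=0:Fam=FAM1];
((ylossA[&&NHX:S=A:Ev=Loss:ts=2],(yB[&&NHX:S=B:Ev=Extant:ts=3],(yC[&&NHX:S=C:Ev=Extant:ts=3])ytr[&&NHX:S=C:Ev=Trans:ts=2])yso[&&NHX:S=B:Ev=SpecOut:ts=2])ye[&&NHX:S=e:Ev=Spec:ts=1],(yCn[&&NHX:S=C:Ev=Extant:ts=3],yD[&&NHX:S=D:Ev=Extant:ts=3])yf[&&NHX:S=f:Ev=Spec:ts=2])yr[&&NHX:S=r:Ev=Spec:ts=0:Fam=FAM2];
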