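set,analyte
discovery,9(10)-epoxy-stearic acid
discovery,9(10)-EpOME
discovery,11(12)-EpETrE
discovery,11(12)-EpETE
discovery,9-oxo-ODE
discovery,13-oxo-ODE
discovery,10-HODE
discovery,12-HODE
discovery,5-HETrE
discovery,15-HETrE
discovery,5-HETE
discovery,15-HETE
discovery,16-HETE
discovery,5-HEPE
discovery,8-HEPE
discovery,4-HDHA
discovery,7-HDHA
discovery,11-HDHA
discovery,"9,10-DiHOME"
discovery,"9,10-DiHODE"
discovery,"5,6-DiHETrE"
discovery,"14,15-DiHETrE"
discovery,"7,8-DiHDPE"
replication,9(10)-epoxy-stearic acid
replication,12(13)-EpODE
replication,14(15)-EpEDE
replication,11(12)-EpETrE
replication,11(12)-EpETE
replication,9-oxo-ODE
replication,13-oxo-ODE
replication,9-HODE
replication,13-HODE
replication,15-HODE
replication,5-HETrE
replication,12-HETrE
replication,5-HEPE
replication,7-HDHA
replication,11-HDHA
replication,"9,10-DiHODE"
replication,"5,6-DiHETrE"
oxyscore,8-HEPE
oxyscore,9(10)-Ep-stearic acid
oxyscore,16-HETE
oxyscore,12(13)-EpODE
oxyscore,12-HETrE
oxyscore,7-HDHA
oxyscore,"9,10-DiHOME"
oxyscore,5-HETE
oxyscore,9-HODE
oxyscore,"14,15-DiHETrE"
oxyscore,"9,10-DiHODE"
oxyscore,5-HETrE
oxyscore,15-HODE
oxyscore,13-oxo-ODE
oxyscore,11(12)-EpETrE
oxyscore,9-oxo-ODE
oxyscore,4-HDHA
oxyscore,13-HODE
oxyscore,12-HODE
oxyscore,"7,8-DiHDPE"
oxyscore,9(10)-EpOME
oxyscore,15-HETE
oxyscore,5-HEPE
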