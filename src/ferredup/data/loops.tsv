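loop_id	ccs	start	end	structure
MCL.EH.9.3.1	d.58.1.1	30	46	1CLF
DS.EG.1.1.12	d.58.1.1	30	36	1BLU
DS.EG.1.1.12	d.161.1.1	-	-	
DS.EG.1.1.12	a.6.1.7	-	-	
DS.EG.1.1.12	b.163.1.1	-	-	
DS.EG.1.1.12	a.127.1.2	-	-	
DS.EG.1.1.12	d.122.1.2	-	-	
DS.HE.5.50.1	d.58.1.1	41	55	1CLF
DS.GH.1.2.10	d.58.1.2	-	-	
DS.EH.8.10.1	d.58.1.3	-	-	
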