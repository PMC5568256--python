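trial_id,label,date,n_control,events_control,n_treated,events_treated
chareancholvanich2013,Chareancholvanich,2013-03-02,40,3,40,1
victor2013,Victor,2013-04-26,64,18,61,15
roh2013,Roh,2013-08-03,48,5,42,5
hamilton2013,Hamilton,2013-08-06,26,8,26,9
boonen2013,Boonen,2013-08-10,82,15,86,26
parratte2013,Parratte,2013-08-15,20,2,20,4
chotanaphuti2013,Chotanaphuti,2013-09-04,40,5,40,2
woolson2014,Woolson,2014-03-07,26,10,22,9
kotela2014,Kotela,2014-06-28,46,14,49,24
pfitzner2014,Pfitzner,2014-07-16,30,13,60,11
yan2014,Yan,2014-09-14,30,13,30,8
abane2015,Abane,2015-01-09,67,22,59,19
molicnik2015,Molicnik,2015-03-04,19,4,19,0
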