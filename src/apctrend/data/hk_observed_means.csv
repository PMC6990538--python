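outcome,age_group,sex,year,mean
bmi,9-11,male,1996,17.2
bmi,9-11,female,1996,16.7
bmi,12-18,male,1996,18.9
bmi,12-18,female,1996,19.0
bmi,9-11,male,1997,17.0
bmi,9-11,female,1997,16.5
bmi,12-18,male,1997,19.6
bmi,12-18,female,1997,19.6
bmi,9-11,male,1998,17.2
bmi,9-11,female,1998,16.6
bmi,12-18,male,1998,19.5
bmi,12-18,female,1998,19.4
sbp,9-11,male,1999,104.6
sbp,9-11,female,1999,104.2
sbp,12-18,male,1999,115.0
sbp,12-18,female,1999,108.9
dbp,9-11,male,1999,60.5
dbp,9-11,female,1999,60.2
dbp,12-18,male,1999,63.5
dbp,12-18,female,1999,62.7
bmi,9-11,male,1999,17.3
bmi,9-11,female,1999,16.6
bmi,12-18,male,1999,19.5
bmi,12-18,female,1999,19.4
sbp,9-11,male,2000,104.8
sbp,9-11,female,2000,104.4
sbp,12-18,male,2000,115.6
sbp,12-18,female,2000,108.6
dbp,9-11,male,2000,59.5
dbp,9-11,female,2000,59.3
dbp,12-18,male,2000,62.8
dbp,12-18,female,2000,62.0
bmi,9-11,male,2000,17.3
bmi,9-11,female,2000,16.6
bmi,12-18,male,2000,19.6
bmi,12-18,female,2000,19.4
sbp,9-11,male,2001,103.9
sbp,9-11,female,2001,104.0
sbp,12-18,male,2001,115.4
sbp,12-18,female,2001,108.3
dbp,9-11,male,2001,58.8
dbp,9-11,female,2001,58.8
dbp,12-18,male,2001,62.1
dbp,12-18,female,2001,61.3
bmi,9-11,male,2001,17.3
bmi,9-11,female,2001,16.7
bmi,12-18,male,2001,19.6
bmi,12-18,female,2001,19.4
sbp,9-11,male,2002,103.7
sbp,9-11,female,2002,103.7
sbp,12-18,male,2002,115.6
sbp,12-18,female,2002,108.1
dbp,9-11,male,2002,58.8
dbp,9-11,female,2002,58.7
dbp,12-18,male,2002,62.4
dbp,12-18,female,2002,61.3
bmi,9-11,male,2002,17.3
bmi,9-11,female,2002,16.7
bmi,12-18,male,2002,19.5
bmi,12-18,female,2002,19.3
sbp,9-11,male,2003,102.3
sbp,9-11,female,2003,102.7
sbp,12-18,male,2003,114.8
sbp,12-18,female,2003,107.6
dbp,9-11,male,2003,58.1
dbp,9-11,female,2003,58.3
dbp,12-18,male,2003,61.9
dbp,12-18,female,2003,60.9
bmi,9-11,male,2003,17.5
bmi,9-11,female,2003,16.8
bmi,12-18,male,2003,19.7
bmi,12-18,female,2003,19.4
sbp,9-11,male,2004,101.9
sbp,9-11,female,2004,101.9
sbp,12-18,male,2004,113.7
sbp,12-18,female,2004,106.9
dbp,9-11,male,2004,57.9
dbp,9-11,female,2004,58.0
dbp,12-18,male,2004,61.5
dbp,12-18,female,2004,60.7
bmi,9-11,male,2004,17.5
bmi,9-11,female,2004,16.8
bmi,12-18,male,2004,19.8
bmi,12-18,female,2004,19.5
sbp,9-11,male,2005,102.0
sbp,9-11,female,2005,102.1
sbp,12-18,male,2005,113.3
sbp,12-18,female,2005,106.6
dbp,9-11,male,2005,57.8
dbp,9-11,female,2005,58.0
dbp,12-18,male,2005,61.2
dbp,12-18,female,2005,60.3
bmi,9-11,male,2005,17.6
bmi,9-11,female,2005,16.9
bmi,12-18,male,2005,19.8
bmi,12-18,female,2005,19.5
sbp,9-11,male,2006,102.7
sbp,9-11,female,2006,102.1
sbp,12-18,male,2006,113.9
sbp,12-18,female,2006,107.1
dbp,9-11,male,2006,58.6
dbp,9-11,female,2006,58.4
dbp,12-18,male,2006,61.9
dbp,12-18,female,2006,61.0
bmi,9-11,male,2006,17.7
bmi,9-11,female,2006,16.9
bmi,12-18,male,2006,19.9
bmi,12-18,female,2006,19.6
sbp,9-11,male,2007,102.5
sbp,9-11,female,2007,102.7
sbp,12-18,male,2007,114.3
sbp,12-18,female,2007,107.6
dbp,9-11,male,2007,58.6
dbp,9-11,female,2007,58.9
dbp,12-18,male,2007,62.0
dbp,12-18,female,2007,61.2
bmi,9-11,male,2007,17.8
bmi,9-11,female,2007,17.0
bmi,12-18,male,2007,19.9
bmi,12-18,female,2007,19.6
sbp,9-11,male,2008,102.7
sbp,9-11,female,2008,102.1
sbp,12-18,male,2008,114.0
sbp,12-18,female,2008,107.2
dbp,9-11,male,2008,58.6
dbp,9-11,female,2008,58.5
dbp,12-18,male,2008,61.8
dbp,12-18,female,2008,61.0
bmi,9-11,male,2008,17.9
bmi,9-11,female,2008,17.1
bmi,12-18,male,2008,20.0
bmi,12-18,female,2008,19.7
sbp,9-11,male,2009,103.0
sbp,9-11,female,2009,102.8
sbp,12-18,male,2009,113.8
sbp,12-18,female,2009,107.4
dbp,9-11,male,2009,58.8
dbp,9-11,female,2009,58.8
dbp,12-18,male,2009,61.8
dbp,12-18,female,2009,61.1
bmi,9-11,male,2009,18.0
bmi,9-11,female,2009,17.1
bmi,12-18,male,2009,20.0
bmi,12-18,female,2009,19.7
sbp,9-11,male,2010,103.6
sbp,9-11,female,2010,102.8
sbp,12-18,male,2010,113.9
sbp,12-18,female,2010,107.6
dbp,9-11,male,2010,59.3
dbp,9-11,female,2010,59.0
dbp,12-18,male,2010,62.0
dbp,12-18,female,2010,61.3
bmi,9-11,male,2010,17.8
bmi,9-11,female,2010,17.0
bmi,12-18,male,2010,20.2
bmi,12-18,female,2010,19.8
sbp,9-11,male,2011,103.1
sbp,9-11,female,2011,102.2
sbp,12-18,male,2011,115.2
sbp,12-18,female,2011,107.9
dbp,9-11,male,2011,58.8
dbp,9-11,female,2011,58.6
dbp,12-18,male,2011,62.3
dbp,12-18,female,2011,61.3
bmi,9-11,male,2011,17.8
bmi,9-11,female,2011,16.9
bmi,12-18,male,2011,20.3
bmi,12-18,female,2011,19.9
sbp,9-11,male,2012,103.6
sbp,9-11,female,2012,102.6
sbp,12-18,male,2012,115.6
sbp,12-18,female,2012,107.9
dbp,9-11,male,2012,59.2
dbp,9-11,female,2012,58.8
dbp,12-18,male,2012,62.3
dbp,12-18,female,2012,61.3
bmi,9-11,male,2012,17.5
bmi,9-11,female,2012,16.7
bmi,12-18,male,2012,20.3
bmi,12-18,female,2012,19.9
sbp,9-11,male,2013,103.6
sbp,9-11,female,2013,102.8
sbp,12-18,male,2013,115.3
sbp,12-18,female,2013,108.2
dbp,9-11,male,2013,59.3
dbp,9-11,female,2013,59.0
dbp,12-18,male,2013,62.4
dbp,12-18,female,2013,61.5
bmi,9-11,male,2013,17.4
bmi,9-11,female,2013,16.6
bmi,12-18,male,2013,20.3
bmi,12-18,female,2013,20.0
sbp,9-11,male,2014,103.4
sbp,9-11,female,2014,102.9
sbp,12-18,male,2014,114.9
sbp,12-18,female,2014,108.1
dbp,9-11,male,2014,59.2
dbp,9-11,female,2014,59.1
dbp,12-18,male,2014,62.6
dbp,12-18,female,2014,61.6
bmi,9-11,male,2014,17.1
bmi,9-11,female,2014,16.3
bmi,12-18,male,2014,20.3
bmi,12-18,female,2014,19.9
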